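import warnings

import numpy as np
import pandas as pd
import pytest

from nicheclim import (EnvironmentalFilter, build_env_hull, sample_pseudo_absences,
                       sample_occurrences)
from nicheclim.sampling import hull_membership_oracle


class TestEnvironmentalFilter:
    def test_colocated_presences_reduce_to_one(self):
        rng = np.random.default_rng(0)
        spread = pd.DataFrame(rng.uniform(0, 10, size=(20, 2)), columns=["a", "b"])
        dup = pd.DataFrame({"a": [3.3, 3.3], "b": [4.4, 4.4]})  # identical env
        X = pd.concat([spread, dup], ignore_index=True)
        kept = EnvironmentalFilter(n_bins=5, seed=0).fit_transform(X)
        assert len(kept) < len(X)
        assert ((kept["a"] == 3.3) & (kept["b"] == 4.4)).sum() <= 1

    def test_spread_presences_all_kept(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": np.arange(10.0), "b": rng.normal(size=10) * 10})
        kept = EnvironmentalFilter(n_bins=50, seed=0).fit_transform(X)
        assert len(kept) == 10

    def test_fitted_filter_is_idempotent(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        f = EnvironmentalFilter(n_bins=10, seed=3).fit(X)
        once = f.transform(X)
        twice = f.transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_kept_count_bounded_and_monotone_in_bins(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        n10 = len(EnvironmentalFilter(n_bins=10, seed=0).fit_transform(X))
        n25 = len(EnvironmentalFilter(n_bins=25, seed=0).fit_transform(X))
        assert n10 <= 10 ** 2
        assert n25 <= 25 ** 2
        assert n10 <= n25  # finer partition keeps at least as many

    def test_degenerate_axis_warns(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            EnvironmentalFilter(n_bins=5, seed=0).fit(X)

    def test_filter_corrects_sampling_bias(self, default_world):
        """With strong observer bias, filtering moves the retained-presence
        environmental distribution closer to the species' niche function
        (mean suitability per environment bin): the KL divergence drops
        relative to the unfiltered presences, in median over replicates."""
        w = default_world
        st = w.stack
        b10, b19 = st.layers["bio10"], st.layers["bio19"]
        sel = w.native_mask & (w.suitability > 0)
        r, c = np.nonzero(sel)
        edges = [np.linspace(np.nanmin(b10[st.mask]), np.nanmax(b10[st.mask]) + 1e-9, 15),
                 np.linspace(np.nanmin(b19[st.mask]), np.nanmax(b19[st.mask]) + 1e-9, 15)]

        def hist(vals10, vals19, wts=None):
            h, _, _ = np.histogram2d(vals10, vals19, bins=edges, weights=wts)
            return h

        mass = hist(b10[r, c], b19[r, c], w.suitability[r, c])
        count = hist(b10[r, c], b19[r, c])
        target = np.zeros_like(mass)
        target[count > 0] = mass[count > 0] / count[count > 0]
        target = target + 1e-6
        target /= target.sum()

        def kl(p, q):
            p = p + 1e-6
            p = p / p.sum()
            return float(np.sum(p * np.log(p / q)))

        improvements = []
        for rep in range(10):
            occ = sample_occurrences(w, 250, w.native_mask, bias_strength=2.0,
                                     seed=1000 + rep)
            rows = occ.records
            env = pd.DataFrame({"bio10": b10[rows["row"], rows["col"]],
                                "bio19": b19[rows["row"], rows["col"]]})
            kept = EnvironmentalFilter(n_bins=25, seed=rep).fit_transform(env)
            kl_raw = kl(hist(env["bio10"], env["bio19"]), target)
            kl_filt = kl(hist(kept["bio10"], kept["bio19"]), target)
            improvements.append(kl_raw - kl_filt)
        assert np.median(improvements) > 0


class TestEnvHull:
    def test_unit_square_membership(self):
        square = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0], "y": [0.0, 1.0, 0.0, 1.0]})
        hull = build_env_hull(square)
        pts = pd.DataFrame({"x": [0.5, 2.0, 0.0], "y": [0.5, 0.5, 0.0]})
        inside = hull.contains(pts)
        assert inside.tolist() == [True, False, True]  # boundary counts inside

    def test_membership_agrees_with_lp_oracle(self):
        rng = np.random.default_rng(0)
        pres = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        hull = build_env_hull(pres)
        pts = rng.normal(scale=1.5, size=(1000, 3))
        got = hull.contains(pd.DataFrame(pts, columns=list("abc")))
        scaled = (pts - hull.center) / hull.scale
        want = hull_membership_oracle(scaled, hull.vertices)
        assert np.array_equal(got, want)

    def test_degenerate_collinear_points_fall_back(self):
        t = np.linspace(0, 1, 10)
        pres = pd.DataFrame({"x": t, "y": 2 * t, "z": -t})
        with pytest.warns(UserWarning, match="degenerate"):
            hull = build_env_hull(pres)
        on_line = pd.DataFrame({"x": [0.5], "y": [1.0], "z": [-0.5]})
        off_line = pd.DataFrame({"x": [0.5], "y": [0.0], "z": [0.0]})
        assert hull.contains(on_line)[0]
        assert not hull.contains(off_line)[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_env_hull(pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]}))


class TestSamplePseudoAbsences:
    @staticmethod
    def _setup(seed=0, n_bg=500):
        rng = np.random.default_rng(seed)
        pres = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        bg = pd.DataFrame(rng.normal(scale=3.0, size=(n_bg, 2)), columns=["a", "b"])
        bg["cell"] = np.arange(len(bg))
        return pres, bg, build_env_hull(pres)

    def test_every_pseudo_absence_outside_hull(self):
        pres, bg, hull = self._setup()
        sets = sample_pseudo_absences(bg, hull, pres, n_pa=50, n_sets=3, seed=1)
        assert len(sets) == 3
        for s in sets:
            assert len(s.pseudo_absences) == 50
            assert not hull.contains(s.pseudo_absences[["a", "b"]]).any()

    def test_master_seed_determinism(self):
        pres, bg, hull = self._setup()
        a = sample_pseudo_absences(bg, hull, pres, n_pa=30, n_sets=2, seed=9)
        b = sample_pseudo_absences(bg, hull, pres, n_pa=30, n_sets=2, seed=9)
        for s1, s2 in zip(a, b):
            pd.testing.assert_frame_equal(s1.pseudo_absences, s2.pseudo_absences)

    def test_sets_are_independent_draws(self):
        pres, bg, hull = self._setup()
        sets = sample_pseudo_absences(bg, hull, pres, n_pa=100, n_sets=2, seed=2)
        assert not sets[0].pseudo_absences["cell"].equals(sets[1].pseudo_absences["cell"])

    def test_n_pa_defaults_to_presence_count(self):
        pres, bg, hull = self._setup()
        sets = sample_pseudo_absences(bg, hull, pres, n_sets=1, seed=0)
        assert len(sets[0].pseudo_absences) == len(pres)

    def test_all_background_inside_hull_reports_count(self):
        rng = np.random.default_rng(3)
        pres = pd.DataFrame(rng.normal(scale=5.0, size=(100, 2)), columns=["a", "b"])
        bg = pd.DataFrame(rng.normal(scale=0.1, size=(50, 2)), columns=["a", "b"])
        hull = build_env_hull(pres)
        with pytest.raises(ValueError, match="only 0 background"):
            sample_pseudo_absences(bg, hull, pres, n_pa=10, n_sets=1, seed=0)

    def test_label_frame_export(self):
        pres, bg, hull = self._setup()
        s = sample_pseudo_absences(bg, hull, pres, n_pa=20, n_sets=1, seed=0)[0]
        frame = s.to_frame()
        assert set(frame["label"]) == {0, 1}
        assert (frame["set_id"] == 0).all()
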