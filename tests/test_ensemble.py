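import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nicheclim import (ClimateStack, EnsembleNicheModel, GridGeometry, SplitSpec,
                       boyce_index, ensemble_forecast, fit_technique, make_splits,
                       make_technique, retain_models,
                       REQUIRED_TECHNIQUES, OPTIONAL_TECHNIQUES)
from nicheclim.ensemble import FittedTechnique


def boyce_oracle(pred_presences, pred_background, n_windows=101):
    """Naive re-implementation: explicit loops over windows, duplicate-F
    collapse, Spearman on the survivors."""
    pe = np.asarray(pred_presences, float)
    pb = np.asarray(pred_background, float)
    lo, hi = pb.min(), pb.max()
    if hi <= lo:
        return float("nan")
    width = (hi - lo) / 10.0
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    F = []
    for m in mids:
        a, b = m - width / 2, m + width / 2
        nb = sum(1 for v in pb if a <= v <= b)
        if nb == 0:
            continue
        np_ = sum(1 for v in pe if a <= v <= b)
        F.append((np_ / len(pe)) / (nb / len(pb)))
    kept = []
    for f in F:
        if not kept or f != kept[-1]:
            kept.append(f)
    if len(kept) < 3 or len(set(kept)) < 2:
        return float("nan")
    return float(stats.spearmanr(np.arange(len(kept)), kept).statistic)


class TestMakeSplits:
    def test_seventy_thirty_floor_arithmetic(self):
        """403 presences at fraction 0.7 split 282 / 121."""
        labels = np.r_[np.ones(403), np.zeros(403)]
        cal, ev = make_splits(len(labels), labels, SplitSpec(seed=0))[0]
        cal_pres = (labels[cal] == 1).sum()
        ev_pres = (labels[ev] == 1).sum()
        assert (cal_pres, ev_pres) == (282, 121)

    def test_partition_and_determinism(self):
        labels = np.r_[np.ones(30), np.zeros(40)]
        s1 = make_splits(70, labels, SplitSpec(seed=5))
        s2 = make_splits(70, labels, SplitSpec(seed=5))
        assert len(s1) == 3
        for (c1, e1), (c2, e2) in zip(s1, s2):
            assert np.array_equal(c1, c2) and np.array_equal(e1, e2)
            assert len(np.intersect1d(c1, e1)) == 0
            assert len(np.union1d(c1, e1)) == 70

    def test_prevalence_preserved_per_repeat(self):
        labels = np.r_[np.ones(100), np.zeros(200)]
        for cal, ev in make_splits(300, labels, SplitSpec(seed=1)):
            assert (labels[cal] == 1).sum() == 70
            assert (labels[cal] == 0).sum() == 140

    def test_tiny_stratum_rejected(self):
        labels = np.r_[np.ones(1), np.zeros(19)]
        with pytest.raises(ValueError, match="stratum"):
            make_splits(20, labels, SplitSpec())


def _separable_toy(seed=0, n=200):
    """Two well-separated (but not point-mass) classes with a graded margin,
    so every technique can produce a ranked score surface."""
    rng = np.random.default_rng(seed)
    x_pres = rng.normal(1.4, 0.7, size=(n, 2))
    x_abs = rng.normal(-1.4, 0.7, size=(n, 2))
    X = np.vstack([x_pres, x_abs])
    y = np.r_[np.ones(n), np.zeros(n)]
    bg = rng.uniform(-4, 4, size=(2000, 2))
    return X, y, bg


class TestTechniques:
    @pytest.mark.parametrize("name", REQUIRED_TECHNIQUES + OPTIONAL_TECHNIQUES)
    def test_predictions_bounded(self, name):
        X, y, bg = _separable_toy()
        ft = fit_technique(name, X, y, seed=0)
        pred = ft.predict(bg)
        assert pred.min() >= 0.0 and pred.max() <= 1.0

    @pytest.mark.parametrize("name", REQUIRED_TECHNIQUES)
    def test_separable_toy_scores_high_boyce(self, name):
        X, y, bg = _separable_toy()
        ft = fit_technique(name, X, y, seed=0)
        b = boyce_index(ft.predict(X[y == 1]), ft.predict(bg))
        assert b >= 0.9

    def test_unknown_technique_lists_supported(self):
        with pytest.raises(ValueError, match="XGB.*GLM"):
            make_technique("XGB")

    def test_single_class_calibration_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_technique("GLM", X, np.ones(30))


class TestBoyceIndex:
    def test_presences_in_top_decile_score_one(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(0, 1, 2000)
        pres = rng.uniform(0.905, 1.0, 100)
        assert boyce_index(pres, bg) == pytest.approx(1.0)

    def test_presences_in_bottom_decile_score_minus_one(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 1, 2000)
        pres = rng.uniform(0.0, 0.095, 100)
        assert boyce_index(pres, bg) == pytest.approx(-1.0)

    def test_null_model_scores_near_zero(self):
        rng = np.random.default_rng(2)
        bg = rng.uniform(0, 1, 5000)
        pres = rng.choice(bg, 1000, replace=False)
        assert abs(boyce_index(pres, bg)) <= 0.3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_window_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        bg = rng.beta(2, 2, size=n)
        pres = rng.beta(3, 1.5, size=max(5, n // 4))
        got = boyce_index(pres, bg)
        want = boyce_oracle(pres, bg)
        assert got == pytest.approx(want, abs=1e-9)

    def test_degenerate_predictions_flagged_not_zero(self):
        assert np.isnan(boyce_index(np.full(10, 0.5), np.full(30, 0.5)))

    def test_minimum_sample_sizes(self):
        with pytest.raises(ValueError):
            boyce_index(np.arange(3) / 3, np.linspace(0, 1, 50))
        with pytest.raises(ValueError):
            boyce_index(np.linspace(0, 1, 10), np.linspace(0, 1, 10))


class TestRetainModels:
    def test_strictly_greater_than_threshold(self):
        means = {"A": 0.71, "B": 0.70, "C": 0.69}
        assert retain_models(means, 0.7) == ["A"]

    def test_descending_order(self):
        means = {"A": 0.75, "B": 0.9, "C": 0.8}
        assert retain_models(means, 0.7) == ["B", "C", "A"]

    def test_empty_retention_warns(self):
        with pytest.warns(UserWarning, match="no technique"):
            assert retain_models({"A": 0.5}, 0.7) == []


def _constant_member(value):
    class _Const:
        def predict_proba(self, X):
            p = np.full(len(X), value)
            return np.column_stack([1 - p, p])

    return FittedTechnique(name=f"C{value}", model=_Const())


class TestEnsembleForecast:
    @staticmethod
    def _stack():
        geom = GridGeometry(5, 5, 1.0)
        mask = np.ones((5, 5), bool)
        mask[0, 0] = False
        rng = np.random.default_rng(0)
        return ClimateStack(geometry=geom,
                            layers={"a": rng.uniform(size=(5, 5)),
                                    "b": rng.uniform(size=(5, 5))},
                            mask=mask)

    def test_single_member_identity_and_mask(self):
        st = self._stack()
        m = ensemble_forecast([_constant_member(0.2)], st, ["a", "b"])
        assert np.nanmax(np.abs(m.values[st.mask] - 0.2)) < 1e-12
        assert np.isnan(m.values[0, 0])

    def test_mean_of_constant_members(self):
        st = self._stack()
        m = ensemble_forecast([_constant_member(0.2), _constant_member(0.6)], st, ["a"])
        assert np.allclose(m.values[st.mask], 0.4)

    def test_bounded_by_member_min_max_and_order_invariant(self):
        st = self._stack()
        X, y, _ = _separable_toy()
        members = [fit_technique(n, X, y) for n in ("GLM", "GBM", "MARS")]
        st2 = ClimateStack(geometry=st.geometry,
                          layers={"x0": st.layers["a"] * 8 - 4, "x1": st.layers["b"] * 8 - 4},
                          mask=st.mask)
        for mem in members:
            pass
        preds = [m.predict(np.column_stack([st2.layers["x0"][st2.mask],
                                            st2.layers["x1"][st2.mask]])) for m in members]
        ens = ensemble_forecast(members, st2, ["x0", "x1"]).values[st2.mask]
        lo = np.min(preds, axis=0)
        hi = np.max(preds, axis=0)
        assert ((ens >= lo - 1e-12) & (ens <= hi + 1e-12)).all()
        ens_rev = ensemble_forecast(members[::-1], st2, ["x0", "x1"]).values[st2.mask]
        assert np.allclose(ens, ens_rev)

    def test_missing_covariate_named(self):
        st = self._stack()
        with pytest.raises(ValueError, match="bio99"):
            ensemble_forecast([_constant_member(0.5)], st, ["a", "bio99"])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ensemble_forecast([], self._stack(), ["a"])


class TestEnsembleNicheModel:
    def test_fit_retain_predict_on_separable_data(self):
        X, y, bg = _separable_toy(seed=3, n=150)
        model = EnsembleNicheModel(techniques=("GLM", "GBM"),
                                   split=SplitSpec(n_repeats=2, seed=0), seed=0)
        model.fit(pd.DataFrame(X, columns=["a", "b"]), y,
                  background=pd.DataFrame(bg, columns=["a", "b"]))
        assert model.retained_  # separable data passes the Boyce bar
        pred = model.predict(pd.DataFrame(bg, columns=["a", "b"]))
        assert pred.min() >= 0 and pred.max() <= 1
        assert len(model.evaluation_.table) == 2 * 2  # techniques x repeats
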