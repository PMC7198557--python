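import numpy as np
import pytest

from nicheclim import (ClimateStack, GridGeometry, ResponseFunction, VariableSpec,
                       generate_climate_grid, make_invasion_scenario,
                       perturb_future, sample_occurrences, true_suitability)
from nicheclim.synthetic import SyntheticWorld, binned_dynamics, default_responses


SPECS = [
    VariableSpec("bio10", 0.0, 30.0, trend="warm_equator", trend_weight=0.8, smoothness=4.0),
    VariableSpec("bio19", 0.0, 1200.0, trend="lat", trend_weight=0.5, smoothness=3.0),
]


class TestGenerateClimateGrid:
    def test_same_seed_is_bit_identical(self):
        a = generate_climate_grid(40, 50, SPECS, seed=3)
        b = generate_climate_grid(40, 50, SPECS, seed=3)
        for v in a.variables:
            assert np.array_equal(a.layers[v], b.layers[v])

    def test_values_respect_spec_ranges(self):
        st = generate_climate_grid(40, 50, SPECS, seed=1)
        assert st.layers["bio10"].min() >= 0.0 and st.layers["bio10"].max() <= 30.0
        assert st.layers["bio19"].min() >= 0.0 and st.layers["bio19"].max() <= 1200.0

    def test_correlation_target_achieved(self):
        specs = SPECS + [VariableSpec("bio1", -5.0, 25.0, correlate_with="bio10",
                                      correlation=0.95, smoothness=3.0)]
        st = generate_climate_grid(100, 100, specs, seed=2)
        r = np.corrcoef(st.layers["bio10"].ravel(), st.layers["bio1"].ravel())[0, 1]
        assert abs(r) >= 0.9

    def test_unattainable_correlation_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            VariableSpec("x", 0, 1, correlate_with="y", correlation=1.5)

    def test_minimum_size_and_variable_count(self):
        with pytest.raises(ValueError):
            generate_climate_grid(5, 50, SPECS, seed=0)
        with pytest.raises(ValueError):
            generate_climate_grid(40, 50, SPECS[:1], seed=0)


class TestTrueSuitability:
    def test_product_identity_and_annihilator(self):
        geom = GridGeometry(2, 2, 1.0)
        stack = ClimateStack(geometry=geom,
                             layers={"bio10": np.array([[30.0, 30.0], [30.0, -50.0]])},
                             mask=np.ones((2, 2), bool))
        suit = true_suitability(stack, [ResponseFunction("bio10", "logistic_increasing",
                                                         {"x0": 18.0, "k": 2.0})])
        assert suit[0, 0] == pytest.approx(1.0)   # rescaled max
        assert suit[1, 1] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_along_increasing_response(self):
        st = generate_climate_grid(30, 30, SPECS, seed=4)
        resp = [ResponseFunction("bio10", "logistic_increasing", {"x0": 15.0, "k": 0.5})]
        suit = true_suitability(st, resp)
        order = np.argsort(st.layers["bio10"].ravel())
        s = suit.ravel()[order]
        assert (np.diff(s) >= -1e-12).all()

    def test_absent_variable_rejected(self):
        st = generate_climate_grid(30, 30, SPECS, seed=4)
        with pytest.raises(ValueError, match="bio99"):
            true_suitability(st, [ResponseFunction("bio99", "gaussian",
                                                   {"center": 0, "width": 1})])

    def test_response_shapes_bounded(self):
        x = np.linspace(-50, 2000, 500)
        for resp in default_responses():
            vals = resp(x)
            assert vals.min() >= 0.0 and vals.max() <= 1.0


def _tiny_world(seed=0):
    st = generate_climate_grid(30, 40, SPECS, seed=seed)
    resp = [ResponseFunction("bio10", "logistic_increasing", {"x0": 15.0, "k": 0.4})]
    suit = true_suitability(st, resp)
    from nicheclim.occurrences import OccurrenceSet
    import pandas as pd
    return SyntheticWorld(stack=st, responses=resp, suitability=suit,
                          native_mask=np.zeros(st.geometry.shape, bool),
                          invaded_mask=np.zeros(st.geometry.shape, bool),
                          occurrences=OccurrenceSet(pd.DataFrame(), aggregated=True),
                          seed=seed)


class TestSampleOccurrences:
    def test_forced_single_cell(self):
        w = _tiny_world()
        w.suitability = np.zeros(w.stack.geometry.shape)
        w.suitability[7, 9] = 1.0
        occ = sample_occurrences(w, 1, np.ones(w.stack.geometry.shape, bool), seed=0)
        assert (occ.records["row"].iloc[0], occ.records["col"].iloc[0]) == (7, 9)

    def test_seeded_determinism(self):
        w = _tiny_world()
        region = np.ones(w.stack.geometry.shape, bool)
        a = sample_occurrences(w, 50, region, seed=5).records
        b = sample_occurrences(w, 50, region, seed=5).records
        assert a.equals(b)

    def test_zero_suitability_cells_never_drawn(self):
        w = _tiny_world()
        w.suitability[w.suitability < 0.4] = 0.0
        region = np.ones(w.stack.geometry.shape, bool)
        occ = sample_occurrences(w, 100, region, seed=1)
        assert (w.suitability[occ.records["row"], occ.records["col"]] > 0).all()

    def test_too_few_eligible_cells_reports_count(self):
        w = _tiny_world()
        w.suitability = np.zeros(w.stack.geometry.shape)
        w.suitability[0, :3] = 1.0
        with pytest.raises(ValueError, match="3 eligible"):
            sample_occurrences(w, 10, np.ones(w.stack.geometry.shape, bool), seed=0)

    def test_sampling_prefers_suitable_cells(self):
        """Mean true suitability at sampled cells beats the region mean."""
        w = _tiny_world(seed=2)
        region = np.ones(w.stack.geometry.shape, bool)
        diffs = []
        for rep in range(20):
            occ = sample_occurrences(w, 200, region, seed=rep)
            mean_sampled = w.suitability[occ.records["row"], occ.records["col"]].mean()
            diffs.append(mean_sampled - w.suitability[region].mean())
        assert np.median(diffs) > 0


class TestInvasionScenario:
    def test_constructed_indices_match_targets(self):
        w = make_invasion_scenario(0.5, 0.0, seed=3)
        assert abs(w.true_unfilling - 0.5) <= 0.05
        assert w.true_expansion <= 0.05

    def test_joint_targets(self):
        w = make_invasion_scenario(0.3, 0.2, seed=3)
        assert abs(w.true_unfilling - 0.3) <= 0.05
        assert abs(w.true_expansion - 0.2) <= 0.05

    def test_identical_environments_give_zero_indices(self):
        w = make_invasion_scenario(0.0, 0.0, seed=1)
        assert w.true_unfilling <= 0.05
        assert w.true_expansion <= 0.05

    def test_masks_disjoint_and_occurrences_on_land(self):
        w = make_invasion_scenario(0.5, 0.0, seed=2)
        assert not (w.native_mask & w.invaded_mask).any()
        r, c = w.occurrences.records["row"], w.occurrences.records["col"]
        assert w.stack.mask[r, c].all()

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            make_invasion_scenario(0.5, 0.5, seed=0)
        with pytest.raises(ValueError):
            make_invasion_scenario(1.2, 0.0, seed=0)


class TestBinnedDynamics:
    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(0)
        env = rng.normal(size=(500, 2))
        w = rng.uniform(0.1, 1, 500)
        exp, unf = binned_dynamics(env, w, env, w, bins=20)
        assert exp == 0.0 and unf == 0.0

    def test_disjoint_sets_give_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(300, 2))
        b = rng.normal(size=(300, 2)) + 50.0
        exp, unf = binned_dynamics(a, np.ones(300), b, np.ones(300), bins=30)
        assert exp == 1.0 and unf == 1.0


class TestPerturbFuture:
    def test_warming_and_precip_scaling(self, default_world):
        st = default_world.stack
        fut = perturb_future(st, warming=2.0, precip_factor=1.1, tag="t")
        m = st.mask
        assert np.allclose(fut.layers["bio10"][m], st.layers["bio10"][m] + 2.0)
        assert np.allclose(fut.layers["bio19"][m], st.layers["bio19"][m] * 1.1)
        assert np.allclose(fut.layers["bio2"][m], st.layers["bio2"][m])
        assert fut.period_tag == "t"
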