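"""Cost-effectiveness comparison, OWSA, PSA draws and CEAC."""

import numpy as np
import pytest

import tccmodel as t
from tccmodel.analysis import _classify, draw_from_spec
from tccmodel.params import CareStage, DistributionSpec, Strategy


class TestClassification:
    def test_cheaper_and_better_is_dominant(self):
        icer, label = _classify(-1467.0, 0.015)
        assert label == "dominant" and icer is None

    def test_costlier_and_worse_is_dominated(self):
        icer, label = _classify(500.0, -0.01)
        assert label == "dominated" and icer is None

    def test_tradeoff_gives_icer(self):
        icer, label = _classify(300.0, 0.015)
        assert label is None
        assert icer == pytest.approx(20000.0)

    def test_degenerate_case_is_null(self):
        icer, label = _classify(0.0, 0.0)
        assert icer is None and label is None


class TestRunDeterministic:
    def test_effect_only_without_economics(self, ps):
        res = t.run_deterministic(ps, ps)
        assert res.delta_cost is None
        assert not res.has_costs
        assert res.delta_qaly > 0

    def test_costs_attached_with_economics(self, ps_eco):
        res = t.run_deterministic(ps_eco, ps_eco)
        assert res.has_costs
        assert res.delta_cost == pytest.approx(
            res.costs[Strategy.DHT].total - res.costs[Strategy.CONVENTIONAL].total
        )

    def test_identical_arms_are_indifferent(self, ps):
        same = ps.copy()
        same.cs_transition[Strategy.DHT] = {
            c: dict(row) for c, row in same.cs_transition[Strategy.CONVENTIONAL].items()
        }
        same.shl_given_cs[Strategy.DHT] = {
            c: row.copy() for c, row in same.shl_given_cs[Strategy.CONVENTIONAL].items()
        }
        import copy

        same.event_rates[Strategy.DHT] = copy.deepcopy(same.event_rates[Strategy.CONVENTIONAL])
        res = t.run_deterministic(same, same)
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)


class TestDistributionDraws:
    def test_beta_moment_match(self):
        """mean 0.5, SE 0.1 implies Beta(12, 12): check sample mean/variance."""
        rng = np.random.default_rng(7)
        spec = DistributionSpec(family="beta", mean=0.5, se=0.1)
        xs = np.array([draw_from_spec(spec, rng) for _ in range(4000)])
        assert xs.mean() == pytest.approx(0.5, abs=0.01)
        assert xs.var() == pytest.approx(0.1**2, rel=0.1)
        assert np.all((xs > 0) & (xs < 1))

    def test_gamma_moment_match(self):
        """SE = 20% of mean implies shape 25, scale mean/25."""
        rng = np.random.default_rng(8)
        spec = DistributionSpec(family="gamma", mean=40.0)
        xs = np.array([draw_from_spec(spec, rng) for _ in range(4000)])
        assert xs.mean() == pytest.approx(40.0, rel=0.02)
        assert xs.std() == pytest.approx(8.0, rel=0.1)
        assert np.all(xs > 0)

    def test_normal_truncated_by_resampling(self):
        rng = np.random.default_rng(9)
        spec = DistributionSpec(family="normal", mean=0.02, se=0.05)
        xs = np.array([draw_from_spec(spec, rng, lo=0.0, hi=1.0) for _ in range(2000)])
        assert np.all((xs >= 0) & (xs <= 1))

    def test_dirichlet_row_mean_preserved(self):
        rng = np.random.default_rng(10)
        mean = np.array([0.16, 0.47, 0.37])
        spec = DistributionSpec(family="dirichlet_row", mean=mean)
        xs = np.array([draw_from_spec(spec, rng) for _ in range(4000)])
        np.testing.assert_allclose(xs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.abs(xs.mean(axis=0) - mean) < 0.01)

    def test_degenerate_row_fixed(self):
        rng = np.random.default_rng(11)
        spec = DistributionSpec(family="dirichlet_row", mean=np.array([1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(draw_from_spec(spec, rng), [1.0, 0.0, 0.0])

    def test_structural_zeros_preserved_in_rows(self):
        rng = np.random.default_rng(12)
        spec = DistributionSpec(family="dirichlet_row", mean=np.array([0.935, 0.0, 0.063, 0.002]))
        xs = np.array([draw_from_spec(spec, rng) for _ in range(50)])
        assert np.all(xs[:, 1] == 0.0)


class TestRegistry:
    def test_fixed_parameters_absent(self, ps_eco):
        pids = [h.pid for h in t.build_registry(ps_eco)]
        assert not any("discount" in p or "cycle_length" in p for p in pids)
        assert "utilities.cs_decrement[CS1]" not in pids
        assert "utilities.shl_decrement[SHL1]" not in pids

    def test_mortality_uses_reported_ci(self, ps):
        h = next(h for h in t.build_registry(ps) if h.pid == "mortality[G4][band2]")
        assert h.spec(ps).bounds() == (0.067, 0.070)

    def test_shared_vs_arm_specific_split(self, ps):
        reg = t.build_registry(ps)
        shared = {h.pid for h in reg if h.shared}
        arm = {h.pid for h in reg if not h.shared}
        assert any(p.startswith("group_transition") for p in shared)
        assert any(p.startswith("cs_transition[dht]") for p in arm)
        assert any(p.startswith("event_rates[conventional]") for p in arm)


class TestOwsa:
    def test_zero_width_bounds_reproduce_base(self, ps):
        base = t.run_deterministic(ps, ps)
        reg = [h for h in t.build_registry(ps) if h.pid == "utilities.cs_decrement[CS3]"]
        reg[0].low = reg[0].high = ps.utilities.cs_decrement[CareStage.CS3]
        entry = t.run_owsa(ps, ps, registry=reg)[0]
        assert entry.delta_qaly_low == pytest.approx(base.delta_qaly, abs=1e-12)
        assert entry.delta_qaly_high == pytest.approx(base.delta_qaly, abs=1e-12)

    def test_base_case_inside_monotone_envelope(self, ps):
        base = t.run_deterministic(ps, ps)
        reg = [h for h in t.build_registry(ps) if h.pid == "utilities.cs_decrement[CS3]"]
        entry = t.run_owsa(ps, ps, registry=reg)[0]
        lo, hi = sorted((entry.delta_qaly_low, entry.delta_qaly_high))
        assert lo <= base.delta_qaly <= hi

    def test_cost_linear_parameter_symmetric_about_base(self, ps_eco):
        """A unit cost enters incremental cost linearly, so symmetric bounds
        produce symmetric incremental-cost excursions."""
        base = t.run_deterministic(ps_eco, ps_eco)
        reg = [h for h in t.build_registry(ps_eco) if h.pid == "economics.disposal_tariff_per_kg"]
        entry = t.run_owsa(ps_eco, ps_eco, registry=reg)[0]
        up = entry.delta_cost_high - base.delta_cost
        down = base.delta_cost - entry.delta_cost_low
        assert up == pytest.approx(down, rel=1e-6)

    def test_rows_skipped(self, ps):
        reg = [h for h in t.build_registry(ps) if h.family == "dirichlet_row"]
        assert t.run_owsa(ps, ps, registry=reg) == []


class TestPsa:
    def test_reproducible_given_seed(self, ps):
        a = t.run_psa(ps, ps, n_iter=8, seed=123)
        b = t.run_psa(ps, ps, n_iter=8, seed=123)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        np.testing.assert_array_equal(a.seeds, b.seeds)

    def test_different_seeds_differ(self, ps):
        a = t.run_psa(ps, ps, n_iter=4, seed=1)
        b = t.run_psa(ps, ps, n_iter=4, seed=2)
        assert not np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_degenerates_to_deterministic_as_se_vanishes(self, ps):
        det = t.run_deterministic(ps, ps)
        reg = [h for h in t.build_registry(ps) if h.family != "dirichlet_row"]
        for h in reg:
            h.se = 0.0
            h.low = h.high = None
        res = t.run_psa(ps, ps, n_iter=5, seed=3, registry=reg)
        np.testing.assert_allclose(res.delta_qaly, det.delta_qaly, atol=1e-6)

    def test_quadrant_shares_sum_to_one(self, ps_eco):
        res = t.run_psa(ps_eco, ps_eco, n_iter=40, seed=4)
        assert sum(res.quadrant_shares().values()) == pytest.approx(1.0, abs=1e-12)

    def test_sample_count_matches_request(self, ps):
        assert t.run_psa(ps, ps, n_iter=6, seed=5).n_iter == 6

    def test_rejects_zero_iterations(self, ps):
        with pytest.raises(ValueError):
            t.run_psa(ps, ps, n_iter=0, seed=1)


@pytest.fixture(scope="module")
def psa_result(ps_eco):
    return t.run_psa(ps_eco, ps_eco, n_iter=60, seed=6)


class TestCeac:

    def test_probabilities_bounded(self, psa_result):
        curve = t.ceac(psa_result, np.arange(0, 100_001, 5000))
        assert np.all((curve.probabilities >= 0) & (curve.probabilities <= 1))

    def test_at_zero_wtp_equals_cost_saving_share(self, psa_result):
        curve = t.ceac(psa_result, [0.0])
        shares = psa_result.quadrant_shares()
        assert curve.probabilities[0] == pytest.approx(shares["SE"] + shares["SW"], abs=1e-12)
        assert curve.probabilities[0] == pytest.approx(np.mean(psa_result.delta_cost <= 0), abs=1e-12)

    def test_limit_at_high_wtp(self, psa_result):
        curve = t.ceac(psa_result, [1e15])
        de, dc = psa_result.delta_qaly, psa_result.delta_cost
        expected = np.mean((de > 0) | ((de == 0) & (dc <= 0)))
        assert curve.probabilities[0] == pytest.approx(expected, abs=1e-12)
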