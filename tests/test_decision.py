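"""Decision analytics: NMB, PSA sampling, CEAC, threshold, scenarios."""

import numpy as np
import pandas as pd
import pytest

import woundcea as w
from woundcea.config import apply_overrides
from woundcea.decision import ARMS, DecisionError, _draw
from woundcea.demographics import DAYS_PER_CYCLE, DAYS_PER_YEAR


@pytest.fixture(scope="module")
def zero_se_config(base_config):
    """Base case with every parameter uncertainty switched off."""
    raw = base_config.to_dict()
    raw["costs"]["npwt_daily"][1] = 0.0
    raw["costs"]["sd_daily"][1] = 0.0
    raw["costs"]["npwt_duration_days"][1] = 0.0
    raw["costs"]["medication_monthly"][1] = 0.0
    raw["mortality"]["smr_se"] = 0.0
    raw["utility"]["decrement_se"] = 0.0
    for arm in ("npwt", "standard", "shared"):
        for item in raw["resource_use"][arm]:
            raw["resource_use"][arm][item][1] = 0.0
    from woundcea.config import _parse

    return _parse(raw)


class TestNMB:
    def test_zero_everything(self):
        assert w.nmb(0.0, 0.0, 25_000.0) == 0.0

    def test_printed_point_arithmetic(self):
        assert w.nmb(3.77, 92_436.0, 20_000.0) == pytest.approx(-17_036.0)

    def test_incremental_from_printed_per_arm_values(self):
        assert (-17_018.0) - (-14_414.0) == pytest.approx(-2_604.0)

    def test_negative_wtp_rejected(self):
        with pytest.raises(DecisionError):
            w.nmb(1.0, 1.0, -1.0)


class TestSampling:
    def test_zero_se_returns_point_estimates(self, zero_se_config):
        spec = w.PSASpec(n_iterations=3, seed=5)
        params = w.sample_parameters(spec, None, zero_se_config, 0)
        assert params["npwt_daily"] == 30.61
        assert params["smr"] == 13.3
        assert params["decrement"] == 0.0095
        assert params["hr"] == 1.07

    def test_gamma_moment_match(self):
        rng = np.random.default_rng(3)
        n = 100_000
        draws = np.array([_draw("gamma", 30.61, 0.18, rng) for _ in range(n)])
        assert draws.mean() == pytest.approx(30.61, abs=3 * 0.18 / np.sqrt(n))
        assert draws.std(ddof=1) == pytest.approx(0.18, rel=0.05)

    def test_lognormal_moment_match(self):
        rng = np.random.default_rng(4)
        draws = np.array([_draw("lognormal", 13.3, 1.45, rng) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(13.3, abs=3 * 1.45 / np.sqrt(50_000))

    def test_deterministic_given_seed_and_iteration(self, base_config):
        spec = w.PSASpec(n_iterations=2, seed=11)
        a = w.sample_parameters(spec, None, base_config, 1)
        b = w.sample_parameters(spec, None, base_config, 1)
        assert a["smr"] == b["smr"] and a["npwt_daily"] == b["npwt_daily"]
        c = w.sample_parameters(spec, None, base_config, 0)
        assert c["smr"] != a["smr"]

    def test_hr_resampled_from_posterior_vector(self, base_config):
        draws = np.log(np.array([0.9, 1.0, 1.1, 1.3]))
        spec = w.PSASpec(n_iterations=1, seed=2)
        hrs = {
            round(w.sample_parameters(spec, draws, base_config, i)["hr"], 10)
            for i in range(50)
        }
        assert hrs <= {round(float(np.exp(d)), 10) for d in draws}
        # permutation invariance: the sampled set ignores draw order
        perm = np.random.default_rng(0).permutation(draws)
        hrs_perm = {
            round(w.sample_parameters(spec, perm, base_config, i)["hr"], 10)
            for i in range(50)
        }
        assert hrs == hrs_perm

    def test_unknown_family_rejected(self):
        with pytest.raises(DecisionError):
            _draw("cauchy", 1.0, 0.1, np.random.default_rng(0))


class TestRunPSA:
    def test_single_zero_se_iteration_equals_deterministic(self, zero_se_config):
        det = w.run_deterministic(zero_se_config)
        draws = w.run_psa(w.PSASpec(n_iterations=1, seed=1), None, zero_se_config)
        for arm in ARMS:
            q, c = draws.arm_arrays(arm)
            assert q[0] == pytest.approx(det[arm].total_qalys, rel=1e-12)
            assert c[0] == pytest.approx(det[arm].total_cost, rel=1e-12)

    def test_same_seed_reproduces(self, base_config):
        a = w.run_psa(w.PSASpec(n_iterations=5, seed=9), None, base_config)
        b = w.run_psa(w.PSASpec(n_iterations=5, seed=9), None, base_config)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_incremental_qalys_follow_hr_sign(self, base_config):
        """Posterior mass above HR 1 implies positive mean QALY gain."""
        draws = w.run_psa(w.PSASpec(n_iterations=100, seed=13), None, base_config)
        q1, _ = draws.arm_arrays("npwt")
        q0, _ = draws.arm_arrays("standard")
        assert (q1 - q0).mean() > 0  # config HR 1.07 > 1


class TestCEAC:
    def _draws_from(self, pairs):
        """pairs: list of (iQALY, iCost) -> PSADraws with standard at origin."""
        rows = []
        for i, (dq, dc) in enumerate(pairs):
            rows.append({"iteration": i, "arm": "npwt", "qalys": dq, "cost_healthcare": dc,
                         "cost_intervention": 0.0, "cost_total": dc})
            rows.append({"iteration": i, "arm": "standard", "qalys": 0.0, "cost_healthcare": 0.0,
                         "cost_intervention": 0.0, "cost_total": 0.0})
        return w.PSADraws(results=pd.DataFrame(rows), spec=w.PSASpec(n_iterations=len(pairs)),
                          baseline_hazard=np.array([0.08]))

    def test_all_draws_favour_standard(self):
        draws = self._draws_from([(-0.1, 100.0)] * 10)
        s = w.ceac(draws, [0, 20_000, 50_000])
        assert (s.table["p_ce"] == 0.0).all()

    def test_ties_count_half(self):
        draws = self._draws_from([(0.0, 0.0)] * 4)
        s = w.ceac(draws, [20_000])
        assert s.probability_cost_effective(20_000) == 0.5

    def test_enumeration_oracle_on_five_draws(self):
        pairs = [(0.01, 100.0), (0.02, 500.0), (-0.01, -50.0), (0.0, 200.0), (0.05, 800.0)]
        lam = 20_000.0
        brute = sum(1.0 if lam * dq - dc > 0 else (0.5 if lam * dq - dc == 0 else 0.0)
                    for dq, dc in pairs) / 5
        draws = self._draws_from(pairs)
        assert w.ceac(draws, [lam]).probability_cost_effective(lam) == pytest.approx(brute)

    def test_inmb_affine_in_wtp_per_iteration(self, base_config):
        draws = w.run_psa(w.PSASpec(n_iterations=20, seed=21), None, base_config)
        q1, c1 = draws.arm_arrays("npwt")
        q0, c0 = draws.arm_arrays("standard")
        lam1, lam2 = 20_000.0, 30_000.0
        inmb1 = (lam1 * q1 - c1) - (lam1 * q0 - c0)
        inmb2 = (lam2 * q1 - c1) - (lam2 * q0 - c0)
        np.testing.assert_allclose(inmb2 - inmb1, (lam2 - lam1) * (q1 - q0), rtol=1e-10)

    def test_reordering_invariance(self):
        pairs = [(0.01, 100.0), (-0.02, 50.0), (0.03, 900.0)]
        a = w.ceac(self._draws_from(pairs), [20_000]).probability_cost_effective(20_000)
        b = w.ceac(self._draws_from(pairs[::-1]), [20_000]).probability_cost_effective(20_000)
        assert a == b

    def test_cheaper_npwt_never_less_acceptable(self):
        pairs = [(0.01, 500.0), (-0.01, 300.0), (0.0, 100.0)]
        shifted = [(dq, dc - 250.0) for dq, dc in pairs]
        p0 = w.ceac(self._draws_from(pairs), [20_000]).probability_cost_effective(20_000)
        p1 = w.ceac(self._draws_from(shifted), [20_000]).probability_cost_effective(20_000)
        assert p1 >= p0

    def test_empty_grid_rejected(self, base_config):
        draws = self._draws_from([(0.0, 0.0)])
        with pytest.raises(DecisionError):
            w.ceac(draws, [])


class TestThreshold:
    def test_identical_costs_break_even_at_one(self, zero_se_config):
        raw = zero_se_config.to_dict()
        raw["costs"]["npwt_daily"] = [4.17, 0.0]  # NPWT priced like standard
        raw["resource_use"]["npwt"] = raw["resource_use"]["standard"]  # same resource use
        from woundcea.config import _parse

        cfg = _parse(raw)
        res = w.threshold_effect(cfg, 20_000.0)
        assert res.achievable and res.required_hr == pytest.approx(1.0, abs=1e-6)

    def test_bisection_matches_analytic_root_on_one_cycle_model(self, base_config):
        """One cycle, no mortality: incremental NMB is affine in p_heal."""
        from woundcea.config import _parse

        raw = base_config.to_dict()
        raw["econ"]["horizon_cycles"] = 1
        raw["econ"]["discount_rate_annual"] = 0.0
        raw["mortality"]["smr"] = 1e-9
        h0 = 0.3
        raw["effectiveness"]["baseline_hazard"] = h0
        cfg = _parse(raw)

        lam = 20_000.0
        c = DAYS_PER_CYCLE
        monthly = cfg.costs.unhealed_monthly_healthcare("npwt")
        monthly0 = cfg.costs.unhealed_monthly_healthcare("standard")
        u_pop = min(
            0.5 * cfg.population_model.predict(cfg.econ.start_age + c / DAYS_PER_YEAR, 1.0)
            + 0.5 * cfg.population_model.predict(cfg.econ.start_age + c / DAYS_PER_YEAR, 0.0),
            1.0,
        )
        delta = cfg.utility_decrement
        p0 = 1 - np.exp(-h0)
        npwt_daily, sd_daily = cfg.costs.npwt_daily_cost, cfg.costs.sd_daily_cost

        # hand-derived affine break-even in p1 (end-of-cycle accrual)
        def inmb(p1):
            q = lam * ((u_pop - delta * (1 - p1)) - (u_pop - delta * (1 - p0))) * (c / DAYS_PER_YEAR)
            cost1 = (1 - p1) * (c * npwt_daily + monthly)
            cost0 = (1 - p0) * (c * sd_daily + monthly0)
            return q - (cost1 - cost0)

        a = lam * delta * (c / DAYS_PER_YEAR) + (c * npwt_daily + monthly)
        const = inmb(0.0)
        p1_star = -const / a  # root of const + a * p1
        hr_star = -np.log(1 - p1_star) / h0
        res = w.threshold_effect(cfg, lam, bracket=(1.0, 10.0))
        assert res.achievable
        assert res.required_hr == pytest.approx(hr_star, abs=1e-5)

    def test_bracket_invariance(self, base_config):
        r1 = w.threshold_effect(base_config, 20_000.0, bracket=(1.0, 5.0))
        r2 = w.threshold_effect(base_config, 20_000.0, bracket=(1.0, 3.0))
        assert r1.required_hr == pytest.approx(r2.required_hr, abs=5e-6)

    def test_unachievable_reported_not_raised(self, base_config):
        raw = base_config.to_dict()
        raw["costs"]["npwt_daily"] = [5000.0, 0.0]
        from woundcea.config import _parse

        res = w.threshold_effect(_parse(raw), 20_000.0)
        assert not res.achievable and res.required_hr is None


class TestScenarios:
    def test_empty_override_matches_base(self, base_config):
        out = w.run_scenarios(base_config, {"base": {}, "same": {}}, n_iterations=10)
        pd.testing.assert_frame_equal(out["base"].table, out["same"].table)

    def test_no_excess_mortality_extends_life(self, base_config):
        cfg1 = apply_overrides(base_config, {"mortality.smr": 1.0})
        base = w.run_deterministic(base_config)
        longer = w.run_deterministic(cfg1)
        assert longer["standard"].total_qalys > base["standard"].total_qalys

    def test_doubled_resource_use_raises_costs(self, base_config):
        cfg2 = apply_overrides(base_config, {"resource_use.multiplier": 2.0})
        base = w.run_deterministic(base_config)
        doubled = w.run_deterministic(cfg2)
        for arm in ARMS:
            assert doubled[arm].healthcare_cost > base[arm].healthcare_cost

    def test_unknown_override_rejected(self, base_config):
        with pytest.raises(Exception):
            w.run_scenarios(base_config, {"bad": {"no.such.key": 1}}, n_iterations=2)
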