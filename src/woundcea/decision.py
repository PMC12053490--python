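"""Decision analytics: PSA, net monetary benefit, CEAC, threshold analysis.

The probabilistic sensitivity analysis (PSA) propagates parameter
uncertainty through the cohort model: each iteration draws a full
parameter set (treatment-effect hazard ratio resampled from the pooled
posterior; costs and resource means from gamma distributions moment-
matched to their mean/s.e. pairs; the SMR from a lognormal; the utility
decrement and NPWT duration from normals truncated at zero), runs both
arms, and records the (QALY, cost) pair per arm. Decision quantities
follow: net monetary benefit NMB = λ·QALYs − cost at willingness-to-pay
λ, the incremental NMB of NPWT over standard dressings, the probability
of cost-effectiveness P(incremental NMB > 0), the cost-effectiveness
acceptability curve over a λ grid, and the break-even effectiveness —
the hazard ratio at which the deterministic incremental NMB crosses
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, apply_overrides
from .engine import (
    ArmResult,
    CostParams,
    arm_summary,
    build_schedule,
    calibrate_baseline_hazard,
    run_cohort,
)
from .estimation import ResourceUseProfile
from .demographics import LifeTable

__all__ = [
    "PSASpec",
    "PSADraws",
    "DecisionSummary",
    "ThresholdResult",
    "nmb",
    "sample_parameters",
    "run_psa",
    "ceac",
    "threshold_effect",
    "run_scenarios",
    "resolve_baseline_hazard",
    "run_deterministic",
]

ARMS = ("npwt", "standard")


class DecisionError(ValueError):
    pass


@dataclass(frozen=True)
class PSASpec:
    """PSA size, seed and the distribution family per parameter class.

    Families are chosen by support: strictly positive quantities with a
    mean/s.e. pair are gamma (moment-matched), the SMR is lognormal,
    quantities that are non-negative but can sit near zero (utility
    decrement, durations) are normal truncated at zero, and the hazard
    ratio is resampled from the pooled posterior draws. Any family can
    be overridden per parameter, or set to "fixed" to freeze it.
    """

    n_iterations: int = 1000
    seed: int = 1
    families: dict = field(
        default_factory=lambda: {
            "hr": "posterior",
            "smr": "lognormal",
            "decrement": "normal_trunc0",
            "npwt_duration_days": "normal_trunc0",
            "npwt_daily": "gamma",
            "sd_daily": "gamma",
            "medication_monthly": "gamma",
            "resource_means": "gamma",
        }
    )

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise DecisionError("n_iterations must be >= 1")


def nmb(qalys: float, cost: float, wtp: float) -> float:
    """Net monetary benefit: λ·QALYs − cost."""
    if wtp < 0:
        raise DecisionError("willingness-to-pay must be >= 0")
    return wtp * qalys - cost


def _draw(family: str, mean: float, se: float, rng: np.random.Generator) -> float:
    """One moment-matched draw; ``se == 0`` always returns the mean."""
    if se == 0 or family == "fixed":
        return mean
    if family == "gamma":
        if mean <= 0:
            return 0.0
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, se**2 / mean))
    if family == "lognormal":
        if mean <= 0:
            raise DecisionError("lognormal family needs a positive mean")
        sigma2 = np.log1p((se / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    if family == "normal_trunc0":
        a = (0.0 - mean) / se
        return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=se, random_state=rng))
    raise DecisionError(f"unknown distribution family '{family}'")


def sample_parameters(
    spec: PSASpec,
    pooled_draws: np.ndarray | None,
    config: ModelConfig,
    iteration: int,
) -> dict:
    """Sampled parameter set for one PSA iteration.

    Deterministic given (spec.seed, iteration). ``pooled_draws`` are
    posterior log-HR samples; when absent the configured point HR is
    used unchanged.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), int(iteration)])
    fam = spec.families
    ses = config.cost_ses
    profile = config.costs.resource_profile

    if pooled_draws is not None and len(pooled_draws) and fam.get("hr", "posterior") == "posterior":
        hr = float(np.exp(rng.choice(pooled_draws)))
    else:
        hr = config.hr

    by_arm = {
        arm: {
            item: (_draw(fam["resource_means"], m, s, rng), s)
            for item, (m, s) in profile.by_arm[arm].items()
        }
        for arm in ARMS
    }
    shared = {
        item: (_draw(fam["resource_means"], m, s, rng), s)
        for item, (m, s) in profile.shared.items()
    }
    med = _draw(fam["medication_monthly"], *profile.medication, rng)

    return {
        "hr": hr,
        "smr": _draw(fam["smr"], config.smr, config.smr_se, rng),
        "decrement": _draw(fam["decrement"], config.utility_decrement, config.utility_decrement_se, rng),
        "npwt_daily": _draw(fam["npwt_daily"], config.costs.npwt_daily_cost, ses["npwt_daily"], rng),
        "sd_daily": _draw(fam["sd_daily"], config.costs.sd_daily_cost, ses["sd_daily"], rng),
        "npwt_duration_days": _draw(
            fam["npwt_duration_days"], config.costs.npwt_duration_days, ses["npwt_duration_days"], rng
        ),
        "medication_monthly": med,
        "resource_profile": ResourceUseProfile(by_arm=by_arm, shared=shared, medication=(med, profile.medication[1])),
    }


def resolve_baseline_hazard(config: ModelConfig, life_table: LifeTable | None = None) -> np.ndarray:
    """The per-cycle baseline healing hazard the config implies.

    A configured value is used directly; otherwise a constant hazard is
    calibrated so the standard arm hits the configured healed fraction at
    the configured cycle under the base-case mortality.
    """
    if config.baseline_hazard is not None:
        return np.atleast_1d(np.asarray(config.baseline_hazard, float))
    table = life_table or config.life_table()
    h0 = calibrate_baseline_hazard(
        config.calibration_target, config.calibration_cycle, config.smr, table, config.econ
    )
    return np.atleast_1d(h0)


def _costs_with(config: ModelConfig, params: dict) -> CostParams:
    return CostParams(
        npwt_daily_cost=params["npwt_daily"],
        sd_daily_cost=params["sd_daily"],
        npwt_duration_days=params["npwt_duration_days"],
        unit_costs=config.costs.unit_costs,
        resource_profile=params["resource_profile"],
        medication_monthly=params["medication_monthly"],
        healed_monthly_cost=config.costs.healed_monthly_cost,
    )


def run_deterministic(
    config: ModelConfig,
    hr: float | None = None,
    baseline_hazard: np.ndarray | None = None,
) -> dict[str, ArmResult]:
    """Point-estimate model run for both arms."""
    table = config.life_table()
    h0 = baseline_hazard if baseline_hazard is not None else resolve_baseline_hazard(config, table)
    sched = build_schedule(hr if hr is not None else config.hr, h0, config.smr, table, config.econ)
    utilities = (config.population_model, config.utility_decrement)
    return {
        arm: arm_summary(run_cohort(sched, config.costs, utilities, config.econ, arm))
        for arm in ARMS
    }


@dataclass
class PSADraws:
    """Per-iteration (QALY, cost) results per arm, plus the sampled HRs."""

    results: pd.DataFrame  # iteration, arm, qalys, cost_healthcare, cost_intervention, cost_total
    spec: PSASpec
    baseline_hazard: np.ndarray

    def arm_arrays(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.results[self.results["arm"] == arm].sort_values("iteration")
        return sub["qalys"].to_numpy(), sub["cost_total"].to_numpy()


def run_psa(
    spec: PSASpec,
    pooled_draws: np.ndarray | None,
    config: ModelConfig,
) -> PSADraws:
    """Monte-Carlo parameter uncertainty propagation.

    The baseline healing hazard is calibrated once and held fixed across
    iterations (it is an internal calibration, not an evidence-based
    parameter); everything else is redrawn per iteration.
    """
    table = config.life_table()
    h0 = resolve_baseline_hazard(config, table)
    rows = []
    for it in range(spec.n_iterations):
        params = sample_parameters(spec, pooled_draws, config, it)
        costs = _costs_with(config, params)
        sched = build_schedule(params["hr"], h0, params["smr"], table, config.econ)
        utilities = (config.population_model, params["decrement"])
        for arm in ARMS:
            res = arm_summary(run_cohort(sched, costs, utilities, config.econ, arm))
            rows.append(
                {
                    "iteration": it,
                    "arm": arm,
                    "hr": params["hr"],
                    "qalys": res.total_qalys,
                    "cost_healthcare": res.healthcare_cost,
                    "cost_intervention": res.intervention_cost,
                    "cost_total": res.total_cost,
                }
            )
    return PSADraws(results=pd.DataFrame(rows), spec=spec, baseline_hazard=h0)


@dataclass
class DecisionSummary:
    """NMB summaries and the acceptability curve over a λ grid.

    ``table`` has one row per λ: per-arm NMB mean and 2.5/97.5
    percentiles, incremental NMB summaries, and the probability that
    NPWT is cost-effective (ties at zero incremental NMB count 0.5).
    """

    table: pd.DataFrame
    wtp_grid: tuple[float, ...]

    def probability_cost_effective(self, wtp: float) -> float:
        row = self.table[self.table["wtp"] == wtp]
        if row.empty:
            raise DecisionError(f"wtp {wtp} not on the evaluated grid")
        return float(row["p_ce"].iloc[0])


def _pct(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def ceac(draws: PSADraws, wtp_grid) -> DecisionSummary:
    """NMB summaries and probability of cost-effectiveness per λ."""
    wtp_grid = tuple(float(w) for w in wtp_grid)
    if not wtp_grid:
        raise DecisionError("willingness-to-pay grid is empty")
    if draws.results.empty:
        raise DecisionError("PSA draws are empty")
    q1, c1 = draws.arm_arrays("npwt")
    q0, c0 = draws.arm_arrays("standard")
    rows = []
    for w in wtp_grid:
        nmb1 = w * q1 - c1
        nmb0 = w * q0 - c0
        inmb = nmb1 - nmb0
        p_ce = float(np.mean(inmb > 0) + 0.5 * np.mean(inmb == 0))
        lo1, hi1 = _pct(nmb1)
        lo0, hi0 = _pct(nmb0)
        loi, hii = _pct(inmb)
        rows.append(
            {
                "wtp": w,
                "nmb_npwt_mean": float(nmb1.mean()),
                "nmb_npwt_lo": lo1,
                "nmb_npwt_hi": hi1,
                "nmb_standard_mean": float(nmb0.mean()),
                "nmb_standard_lo": lo0,
                "nmb_standard_hi": hi0,
                "inmb_mean": float(inmb.mean()),
                "inmb_lo": loi,
                "inmb_hi": hii,
                "p_ce": p_ce,
            }
        )
    return DecisionSummary(table=pd.DataFrame(rows), wtp_grid=wtp_grid)


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even effectiveness of NPWT at a willingness-to-pay.

    ``required_hr`` multiplies the healing hazard; the equivalent
    multiplier on the per-cycle healing probability is reported too,
    since 'probability of healing' can be read on either scale.
    """

    wtp: float
    achievable: bool
    required_hr: float | None
    required_p_heal_multiplier: float | None
    bracket: tuple[float, float]


def threshold_effect(
    config: ModelConfig,
    wtp: float,
    bracket: tuple[float, float] = (1.0, 5.0),
    tol: float = 1e-6,
) -> ThresholdResult:
    """Hazard ratio at which NPWT's deterministic incremental NMB is zero.

    Bisection over the bracket; the incremental NMB is strictly
    increasing in the hazard ratio there (faster healing buys QALYs and
    saves unhealed-state costs). If NPWT already breaks even at the
    lower bracket edge the required multiplier is that edge; if it is
    still not cost-effective at the upper edge the result is flagged
    unachievable rather than raising.
    """
    table = config.life_table()
    h0 = resolve_baseline_hazard(config, table)
    utilities = (config.population_model, config.utility_decrement)

    sched0 = build_schedule(1.0, h0, config.smr, table, config.econ)
    base = arm_summary(run_cohort(sched0, config.costs, utilities, config.econ, "standard"))

    def inmb(hr: float) -> float:
        sched = build_schedule(hr, h0, config.smr, table, config.econ)
        res = arm_summary(run_cohort(sched, config.costs, utilities, config.econ, "npwt"))
        return nmb(res.total_qalys, res.total_cost, wtp) - nmb(base.total_qalys, base.total_cost, wtp)

    lo, hi = bracket
    if not 0 < lo < hi:
        raise DecisionError(f"invalid bracket {bracket}")
    f_lo, f_hi = inmb(lo), inmb(hi)
    if f_lo >= 0:
        root = lo
    elif f_hi < 0:
        return ThresholdResult(wtp=wtp, achievable=False, required_hr=None,
                               required_p_heal_multiplier=None, bracket=bracket)
    else:
        a, b = lo, hi
        while b - a > tol:
            mid = 0.5 * (a + b)
            if inmb(mid) < 0:
                a = mid
            else:
                b = mid
        root = 0.5 * (a + b)

    h = float(h0[0])
    p_mult = float(-np.expm1(-h * root) / -np.expm1(-h)) if h > 0 else root
    return ThresholdResult(
        wtp=wtp, achievable=True, required_hr=float(root),
        required_p_heal_multiplier=p_mult, bracket=bracket,
    )


def run_scenarios(
    config: ModelConfig,
    scenarios: dict[str, dict] | None = None,
    pooled_draws: np.ndarray | None = None,
    n_iterations: int | None = None,
) -> dict[str, DecisionSummary]:
    """Re-run the PSA pipeline under named configuration overrides.

    Every scenario reuses the base seed (same random-number discipline),
    so differences between scenarios reflect the overrides alone.
    Unknown override paths raise.
    """
    scenarios = config.scenarios if scenarios is None else scenarios
    out: dict[str, DecisionSummary] = {}
    for name, overrides in scenarios.items():
        cfg = apply_overrides(config, dict(overrides or {}))
        spec = PSASpec(n_iterations=n_iterations or cfg.psa_iterations, seed=cfg.psa_seed)
        draws = run_psa(spec, pooled_draws, cfg)
        out[name] = ceac(draws, cfg.econ.wtp_grid)
    return out
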