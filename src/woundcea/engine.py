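"""Three-state monthly-cycle cohort model with discounted QALYs and costs.

States: unhealed wound, healed, dead. Everyone starts unhealed. Each
monthly cycle, death (age-indexed, SMR-adjusted, the same in both living
states) is resolved first, then healing among survivors. Utility accrues
at the general-population level in the healed state and at that level
minus the unhealed decrement otherwise. Healthcare costs (resource use,
medication) accrue only while unhealed; dressing costs accrue daily on
the active dressing — the NPWT arm runs the pump for a fixed number of
days of unhealed time and switches to standard dressings afterwards,
pro-rated within the switch cycle. Costs and QALYs are both discounted
at an annual rate.

State membership is evaluated at cycle end by default; an optional
half-cycle correction averages start and end occupancy for accruals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demographics import (
    DAYS_PER_CYCLE,
    DAYS_PER_YEAR,
    LifeTable,
    PopulationUtilityModel,
    adjusted_death_prob,
)
from .estimation import ResourceUseProfile

__all__ = [
    "EconConfig",
    "CostParams",
    "TransitionSchedule",
    "CohortTrace",
    "ArmResult",
    "build_schedule",
    "run_cohort",
    "calibrate_baseline_hazard",
    "arm_summary",
    "microsimulate",
]


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class EconConfig:
    """Horizon, cycle length, discounting and cohort demographics."""

    horizon_cycles: int = 360  # 30 years of monthly cycles
    cycle_days: float = DAYS_PER_CYCLE
    discount_rate_annual: float = 0.035
    start_age: float = 62.9
    prop_male: float = 0.5
    wtp_grid: tuple[float, ...] = (20000.0, 30000.0)
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise EngineError("horizon must be >= 1 cycle")
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise EngineError("discount rate must be in [0, 1)")
        if self.cycle_days <= 0:
            raise EngineError("cycle length must be positive")

    def discount_factor(self, cycle: int) -> float:
        """Discount factor at the end of ``cycle`` (1-indexed)."""
        years = cycle * self.cycle_days / DAYS_PER_YEAR
        return (1.0 + self.discount_rate_annual) ** (-years)


@dataclass(frozen=True)
class CostParams:
    """Unit costs and resource intensities entering the cost streams."""

    npwt_daily_cost: float = 30.61
    sd_daily_cost: float = 4.17
    npwt_duration_days: float = 46.6
    unit_costs: dict = field(default_factory=dict)  # currency per resource item
    resource_profile: ResourceUseProfile | None = None
    medication_monthly: float = 6.18
    healed_monthly_cost: float = 0.0  # healed patients are discharged

    def __post_init__(self) -> None:
        for name in ("npwt_daily_cost", "sd_daily_cost", "npwt_duration_days", "medication_monthly", "healed_monthly_cost"):
            if getattr(self, name) < 0:
                raise EngineError(f"{name} must be >= 0")
        if any(v < 0 for v in self.unit_costs.values()):
            raise EngineError("unit costs must be >= 0")

    def unhealed_monthly_healthcare(self, arm: str) -> float:
        """Monthly healthcare cost while unhealed: resources plus medication."""
        total = self.medication_monthly
        if self.resource_profile is not None:
            means = self.resource_profile.monthly_means(arm)
            for item, mean in means.items():
                try:
                    total += mean * self.unit_costs[item]
                except KeyError:
                    raise EngineError(f"no unit cost configured for resource item '{item}'")
        return total

    def dressing_daily_rate(self, arm: str, cycle: int, cycle_days: float) -> float:
        """Mean daily dressing cost during ``cycle`` (1-indexed) for an arm.

        Standard arm: standard dressings throughout. NPWT arm: pump cost
        for the first ``npwt_duration_days`` of unhealed time, standard
        dressings after, pro-rated within the switch cycle.
        """
        if arm == "standard":
            return self.sd_daily_cost
        start, end = (cycle - 1) * cycle_days, cycle * cycle_days
        frac_npwt = np.clip((self.npwt_duration_days - start) / (end - start), 0.0, 1.0)
        return float(frac_npwt * self.npwt_daily_cost + (1.0 - frac_npwt) * self.sd_daily_cost)


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities over the model horizon."""

    p_heal_standard: np.ndarray
    p_heal_npwt: np.ndarray
    p_die: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_heal_standard", "p_heal_npwt", "p_die"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if np.any((arr < 0) | (arr > 1)):
                raise EngineError(f"{name} outside [0, 1]")
        if not (len(self.p_heal_standard) == len(self.p_heal_npwt) == len(self.p_die)):
            raise EngineError("schedule arrays must share one horizon")

    @property
    def horizon(self) -> int:
        return len(self.p_die)

    def p_heal(self, arm: str) -> np.ndarray:
        if arm == "npwt":
            return self.p_heal_npwt
        if arm == "standard":
            return self.p_heal_standard
        raise EngineError(f"unknown arm '{arm}'")


@dataclass
class CohortTrace:
    """Cycle-by-cycle state occupancy and discounted increment streams."""

    table: pd.DataFrame  # cycle, unhealed, healed, dead, dqaly, dcost_intervention, dcost_healthcare
    arm: str

    def occupancy(self) -> np.ndarray:
        return self.table[["unhealed", "healed", "dead"]].to_numpy()


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime totals for one treatment arm."""

    total_qalys: float
    healthcare_cost: float
    intervention_cost: float
    total_cost: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_cost", self.healthcare_cost + self.intervention_cost)


def build_schedule(
    hr: float,
    baseline_hazard: float | np.ndarray,
    smr: float,
    life_table: LifeTable,
    econ: EconConfig,
) -> TransitionSchedule:
    """Compose the per-cycle transition probabilities.

    The standard arm heals at ``1 - exp(-h0(t))`` per cycle; the NPWT arm
    multiplies the hazard by the pooled hazard ratio. Death probabilities
    come from the life table at the cohort's attained age (cycle start),
    SMR-adjusted on the rate scale. Within a cycle, death is resolved
    before healing, so ``p_heal + p_die`` never needs to stay below 1 as
    a sum — each is a conditional probability in [0, 1].
    """
    if hr <= 0:
        raise EngineError(f"hazard ratio must be positive, got {hr}")
    h0 = np.atleast_1d(np.asarray(baseline_hazard, float))
    if np.any(h0 < 0):
        raise EngineError("baseline hazard must be >= 0")
    H = econ.horizon_cycles
    if h0.size == 1:
        h0 = np.full(H, h0[0])
    elif h0.size < H:
        h0 = np.concatenate([h0, np.full(H - h0.size, h0[-1])])
    else:
        h0 = h0[:H]

    p_die = np.empty(H)
    capped = False
    for t in range(H):
        age = econ.start_age + t * econ.cycle_days / DAYS_PER_YEAR
        age = min(age, life_table.max_age)
        p = adjusted_death_prob(age, smr, life_table, econ.cycle_days)
        if p >= 1.0:
            capped = True
        p_die[t] = min(p, 1.0)
    if capped:
        warnings.warn("SMR-adjusted death probability capped at 1 for late cycles", RuntimeWarning, stacklevel=2)

    return TransitionSchedule(
        p_heal_standard=-np.expm1(-h0),
        p_heal_npwt=-np.expm1(-h0 * hr),
        p_die=p_die,
    )


def run_cohort(
    schedule: TransitionSchedule,
    costs: CostParams,
    utilities: tuple[PopulationUtilityModel, float],
    econ: EconConfig,
    arm: str,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted QALYs and costs.

    QALY increment per cycle: occupancy-weighted utility (healed at the
    population level, unhealed at that level minus the decrement) times
    the cycle length in years, discounted. Healthcare cost accrues on
    unhealed occupancy at the arm's monthly unhealed cost (healed
    occupancy at the configured healed cost, 0 by default); dressing
    (intervention) cost accrues on unhealed occupancy at the arm's daily
    dressing rate times days per cycle.
    """
    if schedule.horizon < econ.horizon_cycles:
        raise EngineError(
            f"schedule covers {schedule.horizon} cycles, config needs {econ.horizon_cycles}"
        )
    pop_util, decrement = utilities
    p_heal = schedule.p_heal(arm)
    p_die = schedule.p_die
    monthly_hc = costs.unhealed_monthly_healthcare(arm)
    cyc_years = econ.cycle_days / DAYS_PER_YEAR
    H = econ.horizon_cycles

    # per-cycle constants (independent of occupancy)
    cycles = np.arange(1, H + 1)
    ages_end = np.minimum(econ.start_age + cycles * cyc_years, 105.0)
    u_pop_arr = np.minimum(
        econ.prop_male * pop_util.predict(ages_end, 1.0)
        + (1.0 - econ.prop_male) * pop_util.predict(ages_end, 0.0),
        1.0,
    )
    disc_arr = (1.0 + econ.discount_rate_annual) ** (-(cycles * cyc_years))
    rate_arr = np.array([costs.dressing_daily_rate(arm, int(t), econ.cycle_days) for t in cycles])

    u, h, d = 1.0, 0.0, 0.0
    rows = np.empty((H, 7))
    for t in range(1, H + 1):
        pd_, ph = p_die[t - 1], p_heal[t - 1]
        u_new = u * (1.0 - pd_) * (1.0 - ph)
        h_new = h * (1.0 - pd_) + u * (1.0 - pd_) * ph
        d_new = d + (u + h) * pd_
        if econ.half_cycle_correction:
            u_w, h_w = 0.5 * (u + u_new), 0.5 * (h + h_new)
        else:
            u_w, h_w = u_new, h_new
        u, h, d = u_new, h_new, d_new

        u_pop, disc = u_pop_arr[t - 1], disc_arr[t - 1]
        dqaly = (u_w * (u_pop - decrement) + h_w * u_pop) * cyc_years * disc
        dcost_int = u_w * econ.cycle_days * rate_arr[t - 1] * disc
        dcost_hc = (u_w * monthly_hc + h_w * costs.healed_monthly_cost) * disc
        rows[t - 1] = (t, u, h, d, dqaly, dcost_int, dcost_hc)

    table = pd.DataFrame(
        rows,
        columns=["cycle", "unhealed", "healed", "dead", "dqaly", "dcost_intervention", "dcost_healthcare"],
    )
    table["cycle"] = table["cycle"].astype(int)
    return CohortTrace(table=table, arm=arm)


def calibrate_baseline_hazard(
    target_cum_healed: float,
    target_cycle: int,
    smr: float,
    life_table: LifeTable,
    econ: EconConfig,
    tol: float = 1e-8,
) -> float:
    """Constant per-cycle healing hazard hitting a target healed fraction.

    Bisection on the standard-arm cumulative healed occupancy at
    ``target_cycle`` (competing with SMR-adjusted mortality), which is
    strictly increasing in the hazard, so the root is unique. Raises when
    the target exceeds what even instant healing could reach given the
    mortality schedule.
    """
    if not 0.0 < target_cum_healed < 1.0:
        raise EngineError("target healed fraction must be in (0, 1)")
    if target_cycle < 1:
        raise EngineError("target cycle must be >= 1")
    econ_t = replace(econ, horizon_cycles=target_cycle)

    def healed_at(h0: float) -> float:
        sched = build_schedule(1.0, h0, smr, life_table, econ_t)
        u, h = 1.0, 0.0
        for t in range(target_cycle):
            pd_, ph = sched.p_die[t], sched.p_heal_standard[t]
            u, h = u * (1 - pd_) * (1 - ph), h * (1 - pd_) + u * (1 - pd_) * ph
        return h

    lo, hi = 0.0, 1.0
    while healed_at(hi) < target_cum_healed:
        hi *= 2.0
        if hi > 1e4:
            raise EngineError(
                f"target healed fraction {target_cum_healed} unreachable by cycle "
                f"{target_cycle} under the mortality schedule"
            )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if healed_at(mid) < target_cum_healed:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi) and abs(healed_at(hi) - target_cum_healed) < tol:
            break
    return 0.5 * (lo + hi)


def arm_summary(trace: CohortTrace) -> ArmResult:
    """Sum the discounted increment streams into lifetime totals."""
    t = trace.table
    return ArmResult(
        total_qalys=float(t["dqaly"].sum()),
        healthcare_cost=float(t["dcost_healthcare"].sum()),
        intervention_cost=float(t["dcost_intervention"].sum()),
    )


def microsimulate(
    schedule: TransitionSchedule,
    arm: str,
    n_patients: int,
    seed: int,
    n_cycles: int | None = None,
) -> np.ndarray:
    """Individual-level Monte-Carlo replica of the cohort update.

    Simulates ``n_patients`` independent patients through the same
    per-cycle probabilities (death resolved before healing) and returns
    the occupancy fractions per cycle, shape (n_cycles, 3). Serves as an
    independent stochastic oracle for :func:`run_cohort`'s deterministic
    trace; the two agree within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    H = n_cycles or schedule.horizon
    p_heal = schedule.p_heal(arm)
    state = np.zeros(n_patients, dtype=np.int8)  # 0 unhealed, 1 healed, 2 dead
    occ = np.empty((H, 3))
    for t in range(H):
        alive = state < 2
        dies = alive & (rng.random(n_patients) < schedule.p_die[t])
        state[dies] = 2
        unhealed = state == 0
        heals = unhealed & (rng.random(n_patients) < p_heal[t])
        state[heals] = 1
        occ[t] = [(state == s).mean() for s in (0, 1, 2)]
    return occ
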