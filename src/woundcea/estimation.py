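"""Trial-derived model parameters: utility decrement, SMR, resource use.

Four quantities enter the cohort model directly from patient-level trial
data:

* the health-state utility decrement of living with an unhealed wound
  (a mixed-effects regression of the EQ-5D index on an unhealed
  indicator, random intercept per patient);
* the standardized mortality ratio (observed deaths over deaths expected
  under the reference life table, integrated over each patient's
  person-time);
* monthly health-resource use means while unhealed, by item (and by arm
  for the primary-care items);
* the mean number of days spent on negative pressure wound therapy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .demographics import DAYS_PER_CYCLE, DAYS_PER_YEAR, LifeTable
from .synthetic import ARM_DEPENDENT_ITEMS, SHARED_ITEMS, SyntheticTrial

__all__ = [
    "UtilityDecrementEstimate",
    "MortalityEstimate",
    "ResourceUseProfile",
    "estimate_utility_decrement",
    "estimate_smr",
    "summarize_resource_use",
    "estimate_npwt_duration",
]


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class UtilityDecrementEstimate:
    """Utility lost per month while unhealed (positive = unhealed worse)."""

    decrement: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MortalityEstimate:
    observed_deaths: int
    expected_deaths: float
    smr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.observed_deaths < 0:
            raise ValueError("observed deaths must be >= 0")
        if not self.expected_deaths > 0:
            raise ValueError("expected deaths must be positive")
        object.__setattr__(self, "smr", self.observed_deaths / self.expected_deaths)


@dataclass
class ResourceUseProfile:
    """Monthly resource-use means (with s.e.) while unhealed.

    ``by_arm[arm][item]`` for the treatment-dependent primary-care items,
    ``shared[item]`` for the treatment-independent secondary-care items,
    ``medication`` for the monthly medication cost. Each value is a
    ``(mean, se)`` pair.
    """

    by_arm: dict[str, dict[str, tuple[float, float]]]
    shared: dict[str, tuple[float, float]]
    medication: tuple[float, float]

    def monthly_means(self, arm: str) -> dict[str, float]:
        """Point-estimate monthly mean per item for one arm."""
        out = {item: mv[0] for item, mv in self.by_arm[arm].items()}
        out.update({item: mv[0] for item, mv in self.shared.items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, items in self.by_arm.items():
            for item, (m, s) in items.items():
                rows.append({"arm": arm, "item": item, "mean": m, "se": s})
        for item, (m, s) in self.shared.items():
            rows.append({"arm": "all", "item": item, "mean": m, "se": s})
        m, s = self.medication
        rows.append({"arm": "all", "item": "medication_cost", "mean": m, "se": s})
        return pd.DataFrame(rows)


def estimate_utility_decrement(trial: SyntheticTrial) -> UtilityDecrementEstimate:
    """Unhealed-state utility decrement from the EQ-5D panel.

    Fits ``index ~ unhealed`` with a random intercept per patient (REML).
    The decrement is the negated unhealed coefficient, so a positive
    value means the unhealed state is worse. When the panel is degenerate
    (near-zero residual variation) or the mixed model cannot be fit, an
    OLS fit with cluster-robust standard errors is used instead.
    """
    df = trial.eq5d
    if df["unhealed"].nunique() < 2:
        raise EstimationError("no variation in healing status across EQ-5D observations")

    # Degenerate, effectively noiseless panel: plain OLS is exact.
    ols = smf.ols("index ~ unhealed", data=df).fit()
    if ols.mse_resid < 1e-16:
        return UtilityDecrementEstimate(
            decrement=-float(ols.params["unhealed"]),
            se=max(float(ols.bse["unhealed"]), 1e-12),
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = smf.mixedlm("index ~ unhealed", data=df, groups=df["patient_id"]).fit(reml=True)
        coef = float(mixed.params["unhealed"])
        se = float(mixed.bse["unhealed"])
        if np.isfinite(coef) and np.isfinite(se) and se > 0:
            return UtilityDecrementEstimate(decrement=-coef, se=se)
    except Exception:
        pass
    robust = smf.ols("index ~ unhealed", data=df).fit(
        cov_type="cluster", cov_kwds={"groups": df["patient_id"]}
    )
    return UtilityDecrementEstimate(
        decrement=-float(robust.params["unhealed"]),
        se=float(robust.bse["unhealed"]),
    )


def expected_deaths(
    ages: np.ndarray,
    person_time_days: np.ndarray,
    reference: LifeTable,
) -> float:
    """Expected deaths under the reference mortality surface.

    Integrates each person's age-specific reference hazard (constant
    within each year of attained age) over their observed person-time,
    at day resolution.
    """
    ages = np.asarray(ages, float)
    pt = np.asarray(person_time_days, float)
    with np.errstate(divide="ignore"):
        h_annual = -np.log1p(-reference.qx)
    total = 0.0
    for a0, days in zip(ages, pt):
        remaining = float(days)
        a = float(a0)
        while remaining > 1e-12:
            idx = min(max(int(np.floor(a)) - reference.min_age, 0), h_annual.size - 1)
            seg = min((np.floor(a) + 1.0 - a) * DAYS_PER_YEAR, remaining)
            total += h_annual[idx] / DAYS_PER_YEAR * seg
            a += seg / DAYS_PER_YEAR
            remaining -= seg
    return float(total)


def estimate_smr(trial: SyntheticTrial, reference: LifeTable) -> MortalityEstimate:
    """Standardized mortality ratio: observed / expected deaths.

    Expected deaths integrate the reference (general-population) hazard
    over each patient's follow-up; the SMR is the cumulative-hazard
    multiplier that reconciles the two, the quantity the cohort model
    applies to the life table on the rate scale.
    """
    pats = trial.patients
    pt = pats["followup_days"].to_numpy(float)
    if pt.sum() <= 0:
        raise EstimationError("no person-time in trial")
    observed = int(pats["died"].sum())
    expected = expected_deaths(pats["age"].to_numpy(float), pt, reference)
    if expected <= 0:
        raise EstimationError("expected deaths are zero; check the life table and ages")
    return MortalityEstimate(observed_deaths=observed, expected_deaths=expected)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, float)
    m = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return m, se


def summarize_resource_use(trial: SyntheticTrial) -> ResourceUseProfile:
    """Per-item monthly resource-use means over unhealed person-time.

    Each patient contributes a monthly rate (total count over unhealed
    months); means and standard errors are taken across patients —
    per arm for the treatment-dependent items, pooled for the
    treatment-independent ones and the medication cost.
    """
    pats = trial.patients
    for arm in ("npwt", "standard"):
        if not (pats["arm"] == arm).any():
            raise EstimationError(f"no patients in the {arm} arm")
    res = trial.resources
    tot = res.groupby(["patient_id", "item"], sort=False)[["count", "unhealed_days"]].sum().reset_index()
    tot = tot.merge(pats[["patient_id", "arm"]], on="patient_id")
    tot = tot[tot["unhealed_days"] > 0]
    if tot.empty:
        raise EstimationError("zero unhealed person-time in trial")
    tot["monthly_rate"] = tot["count"] / (tot["unhealed_days"] / DAYS_PER_CYCLE)

    by_arm: dict[str, dict[str, tuple[float, float]]] = {"npwt": {}, "standard": {}}
    for arm in ("npwt", "standard"):
        sub = tot[tot["arm"] == arm]
        for item in ARM_DEPENDENT_ITEMS:
            by_arm[arm][item] = _mean_se(sub.loc[sub["item"] == item, "monthly_rate"].to_numpy())
    shared = {
        item: _mean_se(tot.loc[tot["item"] == item, "monthly_rate"].to_numpy())
        for item in SHARED_ITEMS
    }
    medication = _mean_se(pats["medication_cost_monthly"].to_numpy())
    return ResourceUseProfile(by_arm=by_arm, shared=shared, medication=medication)


def estimate_npwt_duration(trial: SyntheticTrial) -> tuple[float, float]:
    """Mean and standard error of days on NPWT, over the NPWT arm."""
    sub = trial.patients[trial.patients["arm"] == "npwt"]
    if sub.empty:
        raise EstimationError("NPWT arm is empty")
    return _mean_se(sub["days_on_npwt"].to_numpy(float))
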