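"""Life-table handling, excess-mortality adjustment and population utilities.

The cohort model needs three demographic ingredients:

* a reference life table (annual death probabilities by single year of age),
* a standardized-mortality-ratio (SMR) adjustment applied on the hazard
  scale, so that the adjusted probability never exceeds 1 and scales the
  instantaneous rate rather than the probability, and
* an age/sex quadratic regression predicting general-population EQ-5D
  utility, used as the utility of the healed state.

A synthetic Gompertz-generated life table is bundled for tests and examples
(``woundcea/data/life_table_synthetic.csv``); any CSV with the same dialect
(header ``age,qx`` or ``age,qx_male,qx_female``, ``#`` comment lines) can be
dropped in its place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "PopulationUtilityModel",
    "load_life_table",
    "bundled_life_table",
    "annual_to_cycle_prob",
    "adjusted_death_prob",
    "population_utility",
    "DAYS_PER_YEAR",
    "DAYS_PER_CYCLE",
]

DAYS_PER_YEAR = 365.25
#: Monthly model cycle, one twelfth of a year.
DAYS_PER_CYCLE = DAYS_PER_YEAR / 12.0


class LifeTableError(ValueError):
    """Raised when a life-table file violates the expected format."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` by single year of age.

    Ages must be contiguous and the final age is an absorbing cap
    (``qx == 1``) so that survival beyond the table is impossible.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size != qx.size or ages.size < 2:
            raise LifeTableError("life table needs matching age/qx columns with >= 2 rows")
        if np.any(np.diff(ages) != 1):
            gap = int(np.flatnonzero(np.diff(ages) != 1)[0])
            raise LifeTableError(f"ages not contiguous after age {ages[gap]}")
        bad = np.flatnonzero((qx < 0) | (qx > 1))
        if bad.size:
            raise LifeTableError(f"qx outside [0, 1] at row {bad[0] + 1} (age {ages[bad[0]]})")
        if qx[-1] != 1.0:
            raise LifeTableError(f"final age {ages[-1]} must have qx = 1 (absorbing cap)")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age: float) -> float:
        """Annual death probability at attained (possibly fractional) age.

        The table is indexed by ``floor(age)``; ages past the final row use
        the absorbing cap.
        """
        idx = int(np.floor(age))
        if idx < self.min_age:
            raise LifeTableError(f"age {age} below table range ({self.min_age})")
        idx = min(idx, self.max_age)
        return float(self.qx[idx - self.min_age])

    def annual_hazard(self, age: float) -> float:
        """Constant-within-year hazard implied by the annual probability."""
        q = self.annual_q(age)
        if q >= 1.0:
            return np.inf
        return -np.log1p(-q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def write_csv(self, path: str | Path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


def load_life_table(path: str | Path, sex: str | None = None) -> LifeTable:
    """Read a life-table CSV (``age,qx`` or ``age,qx_male,qx_female``).

    Parameters
    ----------
    path:
        CSV file; lines starting with ``#`` carry provenance and are skipped.
    sex:
        With a two-sex table, ``"male"``/``"female"`` selects a column and
        ``None`` averages the two (a 50:50 unisex table).
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LifeTableError(f"cannot parse life table {path}: {exc}") from exc
    cols = set(df.columns)
    if {"age", "qx"} <= cols:
        qx = df["qx"].to_numpy(float)
    elif {"age", "qx_male", "qx_female"} <= cols:
        if sex == "male":
            qx = df["qx_male"].to_numpy(float)
        elif sex == "female":
            qx = df["qx_female"].to_numpy(float)
        else:
            qx = 0.5 * (df["qx_male"].to_numpy(float) + df["qx_female"].to_numpy(float))
    else:
        raise LifeTableError(
            f"{path}: expected header 'age,qx' or 'age,qx_male,qx_female', got {sorted(cols)}"
        )
    return LifeTable(ages=df["age"].to_numpy(int), qx=qx)


def bundled_life_table() -> LifeTable:
    """The synthetic Gompertz life table shipped with the package."""
    ref = resources.files("woundcea.data") / "life_table_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_life_table(path)


def annual_to_cycle_prob(q_annual: float, cycle_days: float = DAYS_PER_CYCLE) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year: ``1 - (1-q)**(c/365.25)``.
    Composing 12 equal monthly cycles recovers the annual probability
    exactly.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError(f"annual probability {q_annual} outside [0, 1]")
    return 1.0 - (1.0 - q_annual) ** (cycle_days / DAYS_PER_YEAR)


def adjusted_death_prob(
    age: float,
    smr: float,
    table: LifeTable,
    cycle_days: float = DAYS_PER_CYCLE,
) -> float:
    """SMR-adjusted per-cycle death probability at an attained age.

    The SMR multiplies the hazard, not the probability:
    ``1 - exp(-smr * h)`` with ``h = -ln(1 - q_cycle)``, so the result is a
    valid probability for any ``smr > 0`` (capped at 1 when the reference
    probability is itself 1).
    """
    if smr <= 0:
        raise ValueError(f"smr must be positive, got {smr}")
    q_cycle = annual_to_cycle_prob(table.annual_q(age), cycle_days)
    if q_cycle >= 1.0:
        return 1.0
    h = -np.log1p(-q_cycle)
    return float(min(1.0, -np.expm1(-smr * h)))


@dataclass(frozen=True)
class PopulationUtilityModel:
    """Quadratic-in-age, sex-adjusted general-population utility regression.

    ``u(age, male) = intercept + male_coef*male + age_coef*age + age2_coef*age**2``,
    clipped to at most 1. Default coefficients come from the model config;
    zeros here give a flat utility of ``intercept``.
    """

    intercept: float = 1.0
    male_coef: float = 0.0
    age_coef: float = 0.0
    age2_coef: float = 0.0

    def predict(self, age: float | np.ndarray, male: float | np.ndarray) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        u = self.intercept + self.male_coef * np.asarray(male, float) + self.age_coef * age + self.age2_coef * age**2
        return np.minimum(u, 1.0) if u.ndim else float(min(u, 1.0))


def population_utility(
    age: float,
    prop_male: float,
    model: PopulationUtilityModel,
) -> float:
    """Sex-mix-weighted general-population utility at an attained age.

    The utility of the healed state: a weighted mean of the male and female
    predictions with weight ``prop_male``, clipped to at most 1.
    """
    if not 0.0 <= age <= 105.0:
        raise ValueError(f"age {age} outside supported range [0, 105]")
    if not 0.0 <= prop_male <= 1.0:
        raise ValueError(f"prop_male {prop_male} outside [0, 1]")
    u = prop_male * model.predict(age, 1.0) + (1.0 - prop_male) * model.predict(age, 0.0)
    return float(min(u, 1.0))
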