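"""Model configuration: one YAML file holding every model parameter.

Every quantity the cohort model consumes — cohort demographics, economic
settings, costs and resource-use means with their standard errors, the
utility inputs, mortality (SMR and life table), the treatment effect and
the PSA settings — has exactly one home in this file, with explicit
units. ``load_config``/``save_config`` round-trip it; ``config_hash``
fingerprints it so every output artifact can record the configuration
that produced it.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demographics import LifeTable, PopulationUtilityModel, bundled_life_table, load_life_table
from .engine import CostParams, EconConfig
from .estimation import ResourceUseProfile
from .synthetic import ARM_DEPENDENT_ITEMS, SHARED_ITEMS, CohortSpec

__all__ = [
    "ModelConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Configuration problem, reported with the offending field path."""


_MISSING = object()


def _get(d: dict, path: str, typ, default=_MISSING):
    node = d
    parts = path.split(".")
    for key in parts:
        if not isinstance(node, dict) or key not in node:
            if default is not _MISSING:
                return default
            raise ConfigError(f"missing config field '{path}'")
        node = node[key]
    if node is None and default is not _MISSING:
        return default
    try:
        return typ(node)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config field '{path}': {exc}") from exc


def _mean_se_pair(d: dict, path: str) -> tuple[float, float]:
    node = _get(d, path, list)
    if len(node) != 2:
        raise ConfigError(f"config field '{path}' must be [mean, se]")
    m, s = float(node[0]), float(node[1])
    if m < 0 or s < 0:
        raise ConfigError(f"config field '{path}': mean and se must be >= 0")
    return m, s


@dataclass
class ModelConfig:
    """Everything the pipeline needs, parsed and validated."""

    cohort: CohortSpec
    econ: EconConfig
    costs: CostParams
    cost_ses: dict  # se for npwt_daily, sd_daily, npwt_duration, medication
    utility_decrement: float
    utility_decrement_se: float
    population_model: PopulationUtilityModel
    smr: float
    smr_se: float
    life_table_path: str | None
    hr: float
    posterior_draws_path: str | None
    baseline_hazard: float | list | None
    calibration_target: float
    calibration_cycle: int
    psa_iterations: int
    psa_seed: int
    scenarios: dict
    price_year: int
    currency: str
    raw: dict = field(repr=False, default_factory=dict)

    def life_table(self) -> LifeTable:
        if self.life_table_path:
            return load_life_table(self.life_table_path)
        return bundled_life_table()

    def posterior_log_hr_draws(self) -> np.ndarray | None:
        """Pooled-effect posterior draws (log scale) if a path is configured."""
        if not self.posterior_draws_path:
            return None
        df = pd.read_csv(self.posterior_draws_path, comment="#")
        col = "log_hr" if "log_hr" in df.columns else df.columns[0]
        return df[col].to_numpy(float)

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)


def _parse(raw: dict) -> ModelConfig:
    cohort = CohortSpec(
        n_patients=_get(raw, "cohort.n_patients", int, 680),
        mean_age=_get(raw, "cohort.mean_age", float, 62.9),
        sd_age=_get(raw, "cohort.sd_age", float, 12.6),
        prop_large_wound=_get(raw, "cohort.prop_large_wound", float, 0.377),
        prop_inpatient=_get(raw, "cohort.prop_inpatient", float, 0.831),
        prop_tissue_loss=_get(raw, "cohort.prop_tissue_loss", float, 0.784),
        prop_history=_get(raw, "cohort.prop_history", float, 0.168),
        prop_male=_get(raw, "cohort.prop_male", float, 0.5),
        allocation_ratio=_get(raw, "cohort.allocation_ratio", float, 0.5),
    )
    econ = EconConfig(
        horizon_cycles=_get(raw, "econ.horizon_cycles", int, 360),
        cycle_days=_get(raw, "econ.cycle_days", float, 365.25 / 12),
        discount_rate_annual=_get(raw, "econ.discount_rate_annual", float, 0.035),
        start_age=_get(raw, "econ.start_age", float, 62.9),
        prop_male=_get(raw, "econ.prop_male", float, 0.5),
        wtp_grid=tuple(_get(raw, "econ.wtp_grid", list, [20000.0, 30000.0])),
        half_cycle_correction=_get(raw, "econ.half_cycle_correction", bool, False),
    )

    mult = _get(raw, "resource_use.multiplier", float, 1.0)
    if mult < 0:
        raise ConfigError("resource_use.multiplier must be >= 0")

    def _scaled(path: str) -> tuple[float, float]:
        m, s = _mean_se_pair(raw, path)
        return m * mult, s * mult

    by_arm: dict[str, dict[str, tuple[float, float]]] = {}
    for arm in ("npwt", "standard"):
        by_arm[arm] = {
            item: _scaled(f"resource_use.{arm}.{item}") for item in ARM_DEPENDENT_ITEMS
        }
    shared = {item: _scaled(f"resource_use.shared.{item}") for item in SHARED_ITEMS}
    medication = _mean_se_pair(raw, "costs.medication_monthly")
    profile = ResourceUseProfile(by_arm=by_arm, shared=shared, medication=medication)

    unit_costs = _get(raw, "costs.unit_costs", dict)
    missing = [i for i in ARM_DEPENDENT_ITEMS + SHARED_ITEMS if i not in unit_costs]
    if missing:
        raise ConfigError(f"costs.unit_costs missing items {missing}")

    npwt_daily = _mean_se_pair(raw, "costs.npwt_daily")
    sd_daily = _mean_se_pair(raw, "costs.sd_daily")
    npwt_dur = _mean_se_pair(raw, "costs.npwt_duration_days")
    costs = CostParams(
        npwt_daily_cost=npwt_daily[0],
        sd_daily_cost=sd_daily[0],
        npwt_duration_days=npwt_dur[0],
        unit_costs={k: float(v) for k, v in unit_costs.items()},
        resource_profile=profile,
        medication_monthly=medication[0],
        healed_monthly_cost=_get(raw, "costs.healed_monthly_cost", float, 0.0),
    )
    cost_ses = {
        "npwt_daily": npwt_daily[1],
        "sd_daily": sd_daily[1],
        "npwt_duration_days": npwt_dur[1],
        "medication_monthly": medication[1],
    }

    pm = raw.get("utility", {}).get("population_model", {}) or {}
    population_model = PopulationUtilityModel(
        intercept=float(pm.get("intercept", 1.0)),
        male_coef=float(pm.get("male_coef", 0.0)),
        age_coef=float(pm.get("age_coef", 0.0)),
        age2_coef=float(pm.get("age2_coef", 0.0)),
    )

    smr = _get(raw, "mortality.smr", float, 13.3)
    if smr <= 0:
        raise ConfigError("mortality.smr must be positive")

    baseline = raw.get("effectiveness", {}).get("baseline_hazard", None)
    if baseline is not None and np.any(np.atleast_1d(np.asarray(baseline, float)) < 0):
        raise ConfigError("effectiveness.baseline_hazard must be >= 0")

    return ModelConfig(
        cohort=cohort,
        econ=econ,
        costs=costs,
        cost_ses=cost_ses,
        utility_decrement=_get(raw, "utility.decrement", float, 0.0095),
        utility_decrement_se=_get(raw, "utility.decrement_se", float, 0.004),
        population_model=population_model,
        smr=smr,
        smr_se=_get(raw, "mortality.smr_se", float, 1.45),
        life_table_path=_get(raw, "mortality.life_table_path", str, None),
        hr=_get(raw, "effectiveness.hr", float, 1.07),
        posterior_draws_path=_get(raw, "effectiveness.posterior_draws_path", str, None),
        baseline_hazard=baseline,
        calibration_target=_get(raw, "effectiveness.calibration.target_cum_healed", float, 0.55),
        calibration_cycle=_get(raw, "effectiveness.calibration.target_cycle", int, 12),
        psa_iterations=_get(raw, "psa.n_iterations", int, 1000),
        psa_seed=_get(raw, "psa.seed", int, 1),
        scenarios=_get(raw, "scenarios", dict, {}),
        price_year=_get(raw, "price_year", int, 2022),
        currency=_get(raw, "currency", str, "GBP"),
        raw=copy.deepcopy(raw),
    )


def load_config(path: str | Path) -> ModelConfig:
    """Parse and validate a YAML model configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return _parse(raw)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config() -> ModelConfig:
    """The bundled base-case configuration."""
    ref = resources.files("woundcea.data") / "base_case.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)


def config_hash(config: ModelConfig) -> str:
    """Stable fingerprint of the full configuration."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def apply_overrides(config: ModelConfig, overrides: dict) -> ModelConfig:
    """New config with dotted-path overrides applied (unknown paths error)."""
    raw = config.to_dict()
    for path, value in overrides.items():
        node = raw
        parts = path.split(".")
        for key in parts[:-1]:
            if key not in node or not isinstance(node[key], dict):
                raise ConfigError(f"unknown override path '{path}'")
            node = node[key]
        if parts[-1] not in node:
            raise ConfigError(f"unknown override path '{path}'")
        node[parts[-1]] = value
    return _parse(raw)
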