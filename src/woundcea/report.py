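"""Result rendering: lifetime results table, occupancy trace, CEAC data.

Produces the analysis outputs in tidy, plain-text form: a per-arm table
of lifetime QALYs and costs with 95% uncertainty intervals from the PSA
draws, incremental rows, NMB blocks per willingness-to-pay, the
cycle-by-cycle state-occupancy trace, and the acceptability-curve data.
Intervals use the inclusive linear-interpolation percentile definition.
Every artifact written to disk embeds the seed and configuration hash
that produced it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decision import ARMS, PSADraws
from .engine import ArmResult, CohortTrace

__all__ = ["render_results_table", "write_artifact", "trace_frame"]


def _row(quantity: str, values: dict[str, np.ndarray]) -> list[dict]:
    rows = []
    for arm, x in values.items():
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {"quantity": quantity, "arm": arm, "mean": float(np.mean(x)), "lo": float(lo), "hi": float(hi)}
        )
    return rows


def render_results_table(
    base: dict[str, ArmResult],
    draws: PSADraws,
    wtp_set: tuple[float, ...] = (20000.0, 30000.0),
) -> pd.DataFrame:
    """Lifetime totals, incrementals and NMB blocks as a tidy table.

    Means and 2.5/97.5 percentiles come from the PSA draws; the
    deterministic point-estimate run is included as its own column for
    reference. One NMB block per willingness-to-pay value.
    """
    res = draws.results
    arrays = {
        arm: {
            col: res.loc[res["arm"] == arm].sort_values("iteration")[col].to_numpy()
            for col in ("qalys", "cost_total", "cost_healthcare", "cost_intervention")
        }
        for arm in ARMS
    }
    rows: list[dict] = []
    for quantity, col in [
        ("total_qalys", "qalys"),
        ("total_costs", "cost_total"),
        ("healthcare_costs", "cost_healthcare"),
        ("intervention_costs", "cost_intervention"),
    ]:
        rows += _row(quantity, {arm: arrays[arm][col] for arm in ARMS})
    rows += _row("incremental_qalys", {"npwt": arrays["npwt"]["qalys"] - arrays["standard"]["qalys"]})
    rows += _row(
        "incremental_costs", {"npwt": arrays["npwt"]["cost_total"] - arrays["standard"]["cost_total"]}
    )
    for w in wtp_set:
        nmbs = {arm: w * arrays[arm]["qalys"] - arrays[arm]["cost_total"] for arm in ARMS}
        rows += _row(f"nmb_at_{int(w)}", nmbs)
        inmb = nmbs["npwt"] - nmbs["standard"]
        rows += _row(f"inmb_at_{int(w)}", {"npwt": inmb})
        rows.append(
            {
                "quantity": f"p_cost_effective_at_{int(w)}",
                "arm": "npwt",
                "mean": float(np.mean(inmb > 0) + 0.5 * np.mean(inmb == 0)),
                "lo": np.nan,
                "hi": np.nan,
            }
        )
    table = pd.DataFrame(rows)
    point = {
        ("total_qalys", arm): base[arm].total_qalys for arm in base
    } | {
        ("total_costs", arm): base[arm].total_cost for arm in base
    } | {
        ("healthcare_costs", arm): base[arm].healthcare_cost for arm in base
    } | {
        ("intervention_costs", arm): base[arm].intervention_cost for arm in base
    }
    table["point"] = [point.get((q, a), np.nan) for q, a in zip(table["quantity"], table["arm"])]
    return table


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Occupancy and increment streams as written to the trace CSV."""
    return trace.table.copy()


def write_artifact(df: pd.DataFrame, path: str | Path, seed, config_hash: str, version: str) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_hash={config_hash} woundcea_version={version}\n")
        df.to_csv(fh, index=False)
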