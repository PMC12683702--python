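"""Endpoint metrics and the expected-value-of-perfect-information analysis.

The headline metric is the number of "healthy" reefs: reefs whose final coral
cover strictly exceeds 30%. Arranged as an interventions x grazing-scenarios
table of healthy-reef counts, it feeds the EVPI calculation

    EVPI = mean over scenarios of the per-scenario best count
           - best over interventions of the scenario-averaged count,

i.e. "average of the best" minus "best of the averages". A zero EVPI means the
best intervention can be chosen without resolving scenario uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seascape import ConnectivityMatrix

HEALTHY_THRESHOLD = 0.30
_THRESHOLD_ATOL = 1e-9


def healthy_count(final_C: np.ndarray, threshold: float = HEALTHY_THRESHOLD) -> int:
    """Number of reefs with final coral cover strictly above ``threshold``.

    Values within 1e-9 of the threshold are not counted; values outside [0, 1]
    beyond that tolerance are rejected.
    """
    final_C = np.asarray(final_C, dtype=float)
    if np.any(final_C < -_THRESHOLD_ATOL) or np.any(final_C > 1.0 + _THRESHOLD_ATOL):
        raise ValueError("coral covers must lie in [0, 1]")
    return int(np.sum(final_C > threshold + _THRESHOLD_ATOL))


def delta_vs_baseline(
    final: pd.DataFrame, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Per-reef change (intervention - baseline) in final coral and macroalgal
    cover, in percentage points.

    Both frames need columns reef_id, C, M covering the same reef set; rows
    are aligned by reef_id.
    """
    for name, df in (("final", final), ("baseline", baseline)):
        missing = {"reef_id", "C", "M"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} frame missing columns {sorted(missing)}")
    f = final.set_index("reef_id")
    b = baseline.set_index("reef_id")
    if set(f.index) != set(b.index):
        raise ValueError("reef sets differ between intervention and baseline")
    b = b.reindex(f.index)
    return pd.DataFrame(
        {
            "reef_id": f.index.to_numpy(),
            "delta_C_pp": 100.0 * (f["C"].to_numpy() - b["C"].to_numpy()),
            "delta_M_pp": 100.0 * (f["M"].to_numpy() - b["M"].to_numpy()),
        }
    )


def net_migration(K: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Per-reef net immigration implied by a connectivity matrix.

    net_i = sum_{j != i} K[i, j] - sum_{j != i} K[j, i]; self-retention cancels
    and is excluded. The values sum to zero over the network.
    """
    values = K.values if isinstance(K, ConnectivityMatrix) else np.asarray(K, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("connectivity matrix must be square")
    off = values - np.diag(np.diag(values))
    return off.sum(axis=1) - off.sum(axis=0)


@dataclass
class EvpiResult:
    average_of_best: float
    best_of_averages: float
    evpi: float
    scenario_maxima: pd.Series
    intervention_means: pd.Series
    best_intervention: str


def compute_evpi(table: pd.DataFrame) -> EvpiResult:
    """EVPI of a metric table (rows: interventions, columns: scenarios).

    Also returns the per-scenario maxima and per-intervention means used in
    the calculation.
    """
    if table.size == 0:
        raise ValueError("metric table is empty")
    values = table.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("metric table contains non-finite values")
    scenario_maxima = table.max(axis=0)
    intervention_means = table.mean(axis=1)
    average_of_best = float(scenario_maxima.mean())
    best_of_averages = float(intervention_means.max())
    return EvpiResult(
        average_of_best=average_of_best,
        best_of_averages=best_of_averages,
        evpi=average_of_best - best_of_averages,
        scenario_maxima=scenario_maxima,
        intervention_means=intervention_means,
        best_intervention=str(intervention_means.idxmax()),
    )


def format_evpi_report(table: pd.DataFrame, result: EvpiResult | None = None) -> str:
    """Human-readable block mirroring the metric table with its row and column
    averages and the EVPI summary."""
    result = result or compute_evpi(table)
    out = table.copy().astype(float)
    out["avg_across_scenarios"] = result.intervention_means
    col_avg = table.mean(axis=0).astype(float)
    lines = ["Healthy-reef counts (final coral cover > 30%)", ""]
    lines.append(out.round(4).to_string())
    lines.append("")
    lines.append("avg across interventions: " + "  ".join(
        f"{c}={v:.4g}" for c, v in col_avg.items()
    ))
    lines.append(f"average of the best:  {result.average_of_best:.3f}")
    lines.append(f"best of the averages: {result.best_of_averages:.3f}"
                 f"  ({result.best_intervention})")
    lines.append(f"EVPI: {result.evpi:.6g}")
    return "\n".join(lines)
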