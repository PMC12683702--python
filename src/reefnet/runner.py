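"""Orchestration of the factorial analysis.

A single :class:`RunConfig` drives everything: generate (or accept) a
seascape, build the coral connectivity matrix as a weighted average over a
range of pelagic larval durations plus a short-PLD macroalgal matrix, then for
each grazing scenario run a baseline simulation and every configured
management intervention, collect final covers, deltas against baseline and
the interventions x scenarios healthy-reef count table that feeds the EVPI
analysis. The water-quality sweep and the sensitivity grids re-run the same
machinery over extended ranges. Every stage is deterministic given the
config's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import management, metrics, model, params, seascape

logger = logging.getLogger(__name__)

#: Coral PLDs (days) whose kernels are averaged into the working matrix.
DEFAULT_CORAL_PLDS = (10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 130.0)
#: Macroalgal gametes disperse passively for ~5 days.
MACROALGAE_PLD = 5.0

BASELINE_LABEL = "baseline"


@dataclass(frozen=True)
class RunConfig:
    seed: int
    n_reefs: int = 75
    n_grounds: int = 8
    closure_fraction: float = 21.0 / 75.0
    coral_plds: tuple = DEFAULT_CORAL_PLDS
    pld_weights: tuple | None = None  # None: uniform
    macroalgae_pld: float = MACROALGAE_PLD
    kernel: seascape.KernelConfig = field(default_factory=seascape.KernelConfig)
    scenarios: tuple = ("low", "medium", "high")
    intervention_labels: tuple = tuple(management.STANDARD_ARMS)
    a: float = model.DEFAULT_A
    r: float = model.DEFAULT_R
    gamma: float = model.DEFAULT_GAMMA
    mortality: params.MortalityConfig = field(default_factory=params.MortalityConfig)
    t_end: float = model.DEFAULT_T_END
    ic_scenario: str = "empirical"
    healthy_threshold: float = metrics.HEALTHY_THRESHOLD

    def interventions(self) -> dict[str, management.InterventionSpec]:
        unknown = [l for l in self.intervention_labels if l not in management.ALL_ARMS]
        if unknown:
            raise ValueError(f"unknown intervention labels: {unknown}")
        return {l: management.ALL_ARMS[l] for l in self.intervention_labels}


def _subseeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class GridInputs:
    reefs: pd.DataFrame
    K: seascape.ConnectivityMatrix
    N: seascape.ConnectivityMatrix
    initial: model.StateVector


def build_inputs(config: RunConfig, coral_pld: float | None = None) -> GridInputs:
    """Generate the seascape, connectivity matrices and initial state.

    ``coral_pld`` overrides the weighted-average coral matrix with a single-PLD
    matrix (used by the connectivity sensitivity analysis).
    """
    seeds = _subseeds(config.seed, 2 + len(config.coral_plds))
    reefs = seascape.generate_seascape(
        config.n_reefs, config.n_grounds, config.closure_fraction, seed=seeds[0]
    )
    if coral_pld is not None:
        K = seascape.generate_connectivity(
            reefs, coral_pld, config.kernel, seed=seeds[2], kind="coral"
        )
    else:
        mats = [
            seascape.generate_connectivity(
                reefs, pld, config.kernel, seed=seeds[2 + i], kind="coral"
            )
            for i, pld in enumerate(config.coral_plds)
        ]
        K = seascape.weighted_average_connectivity(mats, config.pld_weights)
    N = seascape.generate_connectivity(
        reefs, config.macroalgae_pld, config.kernel, seed=seeds[1], kind="macroalgae"
    )
    initial = seascape.generate_initial_conditions(reefs, config.ic_scenario)
    return GridInputs(reefs, K, N, initial)


@dataclass
class GridResult:
    results: pd.DataFrame          # long format, one row per (scenario, arm, reef)
    metrics: pd.DataFrame          # interventions x scenarios healthy-reef counts
    config: RunConfig
    inputs: GridInputs


def _final_frame(traj: model.Trajectory, reef_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {"reef_id": reef_ids, "M": traj.final.M, "C": traj.final.C}
    )


def run_grid(config: RunConfig, inputs: GridInputs | None = None) -> GridResult:
    """Baseline plus every configured intervention under every grazing
    scenario; returns long-format results and the healthy-count metric table."""
    inputs = inputs or build_inputs(config)
    reefs, ids = inputs.reefs, inputs.reefs["reef_id"].to_numpy()
    arms = config.interventions()
    rows = []
    counts: dict[str, dict[str, int]] = {label: {} for label in arms}
    for scenario in config.scenarios:
        system = params.build_system(
            reefs, inputs.K, inputs.N, scenario, config.mortality,
            a=config.a, r=config.r, gamma=config.gamma,
        )
        runs: list[tuple[str, model.SystemParams]] = [(BASELINE_LABEL, system)]
        for label, spec in arms.items():
            runs.append((label, management.apply_intervention(system, reefs, spec).params))
        baseline_final = None
        for label, sys_run in runs:
            logger.info("running scenario=%s intervention=%s", scenario, label)
            traj = model.integrate(
                inputs.initial, sys_run, t_end=config.t_end, save_every=config.t_end
            )
            final = _final_frame(traj, ids)
            if label == BASELINE_LABEL:
                baseline_final = final
                deltas = pd.DataFrame(
                    {"reef_id": ids,
                     "delta_C_pp": np.zeros(len(ids)),
                     "delta_M_pp": np.zeros(len(ids))}
                )
            else:
                deltas = metrics.delta_vs_baseline(final, baseline_final)
                counts[label][scenario] = metrics.healthy_count(
                    final["C"].to_numpy(), config.healthy_threshold
                )
            frame = pd.DataFrame(
                {
                    "scenario": scenario,
                    "intervention": label,
                    "reef_id": ids,
                    "final_C": final["C"].to_numpy(),
                    "final_M": final["M"].to_numpy(),
                    "final_F": 1.0 - final["C"].to_numpy() - final["M"].to_numpy(),
                    "equilibrium_residual": traj.equilibrium_residual,
                }
            )
            frame["delta_C_pp"] = deltas["delta_C_pp"].to_numpy()
            frame["delta_M_pp"] = deltas["delta_M_pp"].to_numpy()
            rows.append(frame)
    results = pd.concat(rows, ignore_index=True)
    metric_table = pd.DataFrame(
        {s: {label: counts[label].get(s) for label in arms} for s in config.scenarios}
    )
    if metric_table.size:
        metric_table = metric_table.astype(int)
    metric_table.index.name = "intervention"
    return GridResult(results, metric_table, config, inputs)


DEFAULT_SWEEP_PERCENTS = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


@dataclass
class SweepResult:
    results: pd.DataFrame   # (scenario, wq_percent, reef_id, final_C, final_M)
    summary: pd.DataFrame   # per (scenario, wq_percent): mean_C, healthy, n_below_1pct


def water_quality_sweep(
    config: RunConfig,
    percents: tuple = DEFAULT_SWEEP_PERCENTS,
    inputs: GridInputs | None = None,
) -> SweepResult:
    """Network-wide water-quality improvements over a range of percent
    reductions in coral mortality, per grazing scenario.

    Tracks the mean final coral cover, the healthy-reef count and the number
    of reefs left below 1% coral cover.
    """
    inputs = inputs or build_inputs(config)
    ids = inputs.reefs["reef_id"].to_numpy()
    rows, summaries = [], []
    for scenario in config.scenarios:
        system = params.build_system(
            inputs.reefs, inputs.K, inputs.N, scenario, config.mortality,
            a=config.a, r=config.r, gamma=config.gamma,
        )
        for pct in percents:
            spec = management.InterventionSpec("water_quality", wq_percent=float(pct))
            run = management.apply_intervention(system, inputs.reefs, spec)
            traj = model.integrate(
                inputs.initial, run.params, t_end=config.t_end, save_every=config.t_end
            )
            C, M = traj.final.C, traj.final.M
            rows.append(pd.DataFrame(
                {"scenario": scenario, "wq_percent": float(pct), "reef_id": ids,
                 "final_C": C, "final_M": M}
            ))
            summaries.append(
                {"scenario": scenario, "wq_percent": float(pct),
                 "mean_C": float(C.mean()),
                 "healthy": metrics.healthy_count(C, config.healthy_threshold),
                 "n_below_1pct": int(np.sum(C < 0.01))}
            )
    results = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["scenario", "wq_percent", "reef_id",
                                          "final_C", "final_M"]))
    return SweepResult(results, pd.DataFrame(summaries))


@dataclass
class SensitivityResult:
    cells: pd.DataFrame          # one row per grid cell with its EVPI
    metric_tables: dict          # cell key -> interventions x scenarios table
    pooled_evpi: float           # EVPI over the scenario axis pooled across cells
    pooled_table: pd.DataFrame


def sensitivity_grid(
    config: RunConfig,
    a_values: tuple,
    d_med_values: tuple,
    pld_values: tuple,
    ic_scenarios: tuple = ("empirical",),
) -> SensitivityResult:
    """Full factorial re-run over overgrowth rate a, median mortality, coral
    PLD (single-PLD matrices) and initial-condition scenario.

    Per cell, the full scenario x intervention grid is run and its EVPI over
    the grazing-scenario axis recorded; a pooled EVPI treats every
    (cell, scenario) combination as one uncertainty column.
    """
    for name, grid in (("a_values", a_values), ("d_med_values", d_med_values),
                       ("pld_values", pld_values), ("ic_scenarios", ic_scenarios)):
        if len(grid) == 0:
            raise ValueError(f"{name} must be non-empty")
    cell_rows = []
    tables: dict[tuple, pd.DataFrame] = {}
    pooled_cols = {}
    for pld in pld_values:
        for ic in ic_scenarios:
            base = replace(config, ic_scenario=ic)
            inputs = build_inputs(base, coral_pld=float(pld))
            for a in a_values:
                for d_med in d_med_values:
                    cfg = replace(
                        base, a=float(a),
                        mortality=params.MortalityConfig(
                            d_med=float(d_med), spread=config.mortality.spread
                        ),
                    )
                    grid_res = run_grid(cfg, inputs=inputs)
                    key = (float(a), float(d_med), float(pld), ic)
                    tables[key] = grid_res.metrics
                    evpi = metrics.compute_evpi(grid_res.metrics)
                    cell_rows.append(
                        {"a": float(a), "d_med": float(d_med), "pld": float(pld),
                         "ic_scenario": ic, "evpi": evpi.evpi,
                         "best_intervention": evpi.best_intervention}
                    )
                    for scenario in grid_res.metrics.columns:
                        pooled_cols[f"a={a};d={d_med};pld={pld};ic={ic};{scenario}"] = (
                            grid_res.metrics[scenario]
                        )
    pooled_table = pd.DataFrame(pooled_cols)
    pooled = metrics.compute_evpi(pooled_table)
    return SensitivityResult(
        cells=pd.DataFrame(cell_rows),
        metric_tables=tables,
        pooled_evpi=pooled.evpi,
        pooled_table=pooled_table,
    )


def network_diagnostics(K: seascape.ConnectivityMatrix | np.ndarray) -> dict:
    """Weak-component count and degree summaries of the dispersal graph.

    Reefs i and j are linked when either directed entry is positive;
    self-loops are ignored.
    """
    values = K.values if isinstance(K, seascape.ConnectivityMatrix) else np.asarray(K, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("connectivity matrix must be square")
    n = values.shape[0]
    adj = (values > 0) | (values.T > 0)
    np.fill_diagonal(adj, False)
    G = nx.from_numpy_array(adj)
    degrees = np.array([deg for _, deg in G.degree()])
    return {
        "n_reefs": n,
        "n_weak_components": nx.number_connected_components(G),
        "degree_mean": float(degrees.mean()) if n else 0.0,
        "degree_max": int(degrees.max()) if n else 0,
        "density": float(nx.density(G)),
    }
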