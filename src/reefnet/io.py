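"""CSV readers/writers, configuration validation and run manifests.

All artifacts are plain CSV with fixed column orders; readers validate and
reject malformed input rather than coercing it. Percent-scale numbers appear
only in reports; everything in memory is a proportion in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, params, runner, seascape

PACKAGE_VERSION = "0.1.0"


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


# ---------------------------------------------------------------- reef table

def write_reef_table(reefs: pd.DataFrame, path) -> None:
    seascape.validate_reef_table(reefs)
    out = reefs[seascape.REEF_COLUMNS].copy()
    out["closure_id"] = out["closure_id"].fillna("")
    out.to_csv(path, index=False)


def read_reef_table(path) -> pd.DataFrame:
    reefs = pd.read_csv(
        path,
        dtype={"fishing_ground": str, "closure_id": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in seascape.REEF_COLUMNS if c not in reefs.columns]
    if missing:
        raise seascape.ReefTableValidationError(
            f"{path}: missing columns {missing}"
        )
    reefs = reefs[seascape.REEF_COLUMNS].copy()
    # empty closure field means "not in a closure", not an empty-string category
    reefs["closure_id"] = reefs["closure_id"].replace("", None).astype(object)
    for col in ("lon", "lat", "herbivore_density", "sediment_index",
                "initial_coral", "initial_macroalgae"):
        reefs[col] = pd.to_numeric(reefs[col], errors="raise")
    reefs["reef_id"] = pd.to_numeric(reefs["reef_id"], errors="raise")
    seascape.validate_reef_table(reefs)
    return reefs


# ---------------------------------------------------------- connectivity csv

def write_matrix(m: seascape.ConnectivityMatrix, path, seed: int | None = None) -> None:
    """Square CSV with reef-id header row/column and a metadata comment line."""
    meta = f"# kind={m.kind} pld_days={m.pld_days}"
    if seed is not None:
        meta += f" seed={seed}"
    frame = pd.DataFrame(m.values, index=m.reef_ids, columns=m.reef_ids)
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        frame.to_csv(fh, index_label="reef_id")


def read_matrix(path, reefs: pd.DataFrame | None = None) -> seascape.ConnectivityMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata comment line")
        meta = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
        frame = pd.read_csv(fh, index_col=0)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square {values.shape}")
    if np.any(~np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ValueError(f"{path}: non-finite entry at row {i}, col {j}")
    row_ids = frame.index.to_numpy()
    col_ids = pd.to_numeric(pd.Index(frame.columns), errors="coerce").to_numpy()
    if np.any(pd.isna(col_ids)) or not np.array_equal(row_ids, col_ids):
        raise ValueError(f"{path}: row and column reef ids disagree")
    if reefs is not None and not np.array_equal(row_ids, reefs["reef_id"].to_numpy()):
        raise ValueError(
            f"{path}: matrix reef order does not match the reef table "
            "(reorder is not applied silently)"
        )
    pld: float | str = meta.get("pld_days", "")
    if pld != seascape.WEIGHTED_AVERAGE:
        pld = float(pld)
    return seascape.ConnectivityMatrix(values, row_ids, meta.get("kind", "coral"), pld)


# ------------------------------------------------------------- configuration

_CONFIG_KEYS = {f.name for f in fields(runner.RunConfig)}
_KERNEL_KEYS = {f.name for f in fields(seascape.KernelConfig)}
_MORT_KEYS = {f.name for f in fields(params.MortalityConfig)}


def validate_config(raw: dict) -> runner.RunConfig:
    """Build a RunConfig from a raw mapping: defaults injected, unknown keys
    and out-of-range values rejected, seed mandatory."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("configuration must set an explicit seed")
    kw = dict(raw)
    if "kernel" in kw:
        k = kw["kernel"]
        bad = set(k) - _KERNEL_KEYS
        if bad:
            raise ConfigError(f"unknown kernel keys: {sorted(bad)}")
        try:
            kw["kernel"] = seascape.KernelConfig(**k)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid kernel settings: {exc}") from exc
    if "mortality" in kw:
        m = kw["mortality"]
        bad = set(m) - _MORT_KEYS
        if bad:
            raise ConfigError(f"unknown mortality keys: {sorted(bad)}")
        try:
            kw["mortality"] = params.MortalityConfig(**m)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid mortality settings: {exc}") from exc
    for key in ("coral_plds", "pld_weights", "scenarios", "intervention_labels"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    try:
        config = runner.RunConfig(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    for scenario in config.scenarios:
        if scenario not in params.SCENARIO_MEDIANS:
            raise ConfigError(f"unknown grazing scenario {scenario!r}")
    if len(set(config.intervention_labels)) != len(config.intervention_labels):
        raise ConfigError("duplicate intervention labels")
    config.interventions()  # resolves labels, raises on unknown
    if config.ic_scenario not in seascape.IC_SCENARIOS:
        raise ConfigError(f"unknown ic_scenario {config.ic_scenario!r}")
    if config.t_end <= 0:
        raise ConfigError("t_end must be positive")
    if not 0.0 <= config.healthy_threshold <= 1.0:
        raise ConfigError("healthy_threshold must lie in [0, 1]")
    return config


def load_config(path) -> runner.RunConfig:
    """Read a YAML or JSON configuration file (format chosen by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return validate_config(raw or {})


def config_to_dict(config: runner.RunConfig) -> dict:
    d = asdict(config)
    d["kernel"] = asdict(config.kernel)
    d["mortality"] = asdict(config.mortality)
    return d


def config_hash(config: runner.RunConfig) -> str:
    """Stable digest of the resolved configuration (key order independent)."""
    canon = json.dumps(config_to_dict(config), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ------------------------------------------------------------------ manifest

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str = PACKAGE_VERSION
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    resolved_config: dict = field(default_factory=dict)

    def record(self, stage: str, path) -> None:
        self.outputs[stage] = str(path)

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")


def new_manifest(config: runner.RunConfig) -> RunManifest:
    return RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        resolved_config=config_to_dict(config),
    )


# ------------------------------------------------------------------- outputs

def write_grid_outputs(result: runner.GridResult, out_dir) -> RunManifest:
    """Write the full set of grid artifacts and a traceable manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = new_manifest(result.config)

    reefs_path = out / "reef_table.csv"
    write_reef_table(result.inputs.reefs, reefs_path)
    manifest.record("reef_table", reefs_path)

    k_path, n_path = out / "connectivity_coral.csv", out / "connectivity_macroalgae.csv"
    write_matrix(result.inputs.K, k_path, seed=result.config.seed)
    write_matrix(result.inputs.N, n_path, seed=result.config.seed)
    manifest.record("connectivity_coral", k_path)
    manifest.record("connectivity_macroalgae", n_path)

    results_path = out / "results.csv"
    result.results.to_csv(results_path, index=False)
    manifest.record("results", results_path)

    metrics_path = out / "healthy_counts.csv"
    result.metrics.to_csv(metrics_path)
    manifest.record("healthy_counts", metrics_path)

    if result.metrics.size:
        evpi_path = out / "evpi_report.txt"
        evpi_path.write_text(metrics.format_evpi_report(result.metrics) + "\n")
        manifest.record("evpi_report", evpi_path)

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest
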