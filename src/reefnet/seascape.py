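"""Synthetic seascape, connectivity and initial-condition generators.

The generators emulate the statistical structure of a clustered tropical reef
seascape surveyed at ~75 sites: reefs grouped around customary fishing-ground
centroids, a minority sitting inside periodically harvested fishery closures,
right-skewed herbivore densities, sediment exposure decaying away from the
coast, and distance-decay propagule dispersal whose range scales with pelagic
larval duration (PLD). They exist so that the full analysis pipeline is
runnable and testable without any survey or hydrodynamic data.

Connectivity uses an isotropic exponential kernel

    k_ij = p0 * exp(-dist_ij / (speed_km_per_day * pld_days))

optionally roughened by multiplicative lognormal noise and pruned below a
threshold. This is a deliberate stand-in for a Lagrangian current-driven
simulation: it preserves the analysis-relevant features (PLD-dependent range,
sparse long-distance links, graph fragmentation at short PLD) and nothing
else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import pairwise_distance_km
from .model import StateVector

REEF_COLUMNS = [
    "reef_id", "lon", "lat", "fishing_ground", "closure_id",
    "herbivore_density", "sediment_index", "initial_coral", "initial_macroalgae",
]

#: Marker used as ``pld_days`` of a weighted-average matrix.
WEIGHTED_AVERAGE = "weighted-average"

# Seascape envelope (decimal degrees): a ~130 x 90 km box in the tropics.
_LON_RANGE = (178.3, 179.5)
_LAT_RANGE = (-17.8, -17.0)
_REEF_SCATTER_DEG = 0.05       # within-ground scatter sd
_COAST_LAT = -17.9             # simulated coast axis (southern boundary)
_SEDIMENT_SCALE = 10.0         # index value at the coast
_SEDIMENT_DECAY_KM = 20.0      # e-folding distance of the coastal plume
_SEDIMENT_NOISE_SD = 0.3
_DENSITY_MEDIAN = 100.0        # kg/ha, median herbivore biomass density
_DENSITY_SDLOG = 0.75


class ReefTableValidationError(ValueError):
    """A reef table violated its schema or invariants."""


@dataclass(frozen=True)
class KernelConfig:
    """Distance-decay dispersal kernel settings.

    p0: settlement rate at zero distance (self-retention scale), in (0, 1].
    speed_km_per_day: kernel e-folding range gained per PLD day (an effective
        decay scale, not an advection speed).
    noise_sd: sd of multiplicative lognormal noise roughening the kernel.
    prune_threshold: entries below this are zeroed (no modeled dispersal).
    """

    p0: float = 0.65
    speed_km_per_day: float = 0.03
    noise_sd: float = 0.3
    prune_threshold: float = 1e-5

    def __post_init__(self):
        if not 0.0 < self.p0 <= 1.0:
            raise ValueError("p0 must be in (0, 1]")
        if self.speed_km_per_day <= 0:
            raise ValueError("speed_km_per_day must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.prune_threshold < self.p0:
            raise ValueError("prune_threshold must be in [0, p0)")


@dataclass
class ConnectivityMatrix:
    """Square matrix of settlement rates: entry [i, j] is the probability-like
    rate of propagules produced at reef j settling at reef i."""

    values: np.ndarray
    reef_ids: np.ndarray
    kind: str  # "coral" | "macroalgae"
    pld_days: float | str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.reef_ids = np.asarray(self.reef_ids)
        n = self.reef_ids.size
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} reef ids"
            )
        if np.any(~np.isfinite(self.values)):
            raise ValueError("connectivity entries must be finite (no NaN)")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("connectivity entries must lie in [0, 1]")
        if self.kind not in ("coral", "macroalgae"):
            raise ValueError("kind must be 'coral' or 'macroalgae'")
        if isinstance(self.pld_days, str):
            if self.pld_days != WEIGHTED_AVERAGE:
                raise ValueError(f"pld_days marker must be {WEIGHTED_AVERAGE!r}")
        elif self.pld_days <= 0:
            raise ValueError("pld_days must be positive")

    @property
    def n_reefs(self) -> int:
        return self.reef_ids.size

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            self.values.copy(), self.reef_ids.copy(), self.kind, self.pld_days
        )


def validate_reef_table(reefs: pd.DataFrame) -> None:
    """Assert the per-field invariants of a reef table; raise naming the
    offending reef and column."""
    missing = [c for c in REEF_COLUMNS if c not in reefs.columns]
    if missing:
        raise ReefTableValidationError(f"missing columns: {missing}")
    if reefs["reef_id"].duplicated().any():
        dup = reefs.loc[reefs["reef_id"].duplicated(), "reef_id"].iloc[0]
        raise ReefTableValidationError(f"duplicate reef_id {dup!r}")
    for col in ("lon", "lat"):
        if not np.all(np.isfinite(reefs[col].to_numpy(dtype=float))):
            bad = reefs.loc[~np.isfinite(reefs[col].to_numpy(dtype=float)), "reef_id"].iloc[0]
            raise ReefTableValidationError(f"non-finite {col} at reef_id {bad!r}")
    if np.any(np.abs(reefs["lat"].to_numpy(dtype=float)) > 90.0):
        raise ReefTableValidationError("latitude outside [-90, 90]")
    for col in ("herbivore_density", "sediment_index"):
        v = reefs[col].to_numpy(dtype=float)
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            bad = reefs.loc[(v < 0) | ~np.isfinite(v), "reef_id"].iloc[0]
            raise ReefTableValidationError(f"invalid {col} at reef_id {bad!r}")
    cov = reefs[["initial_coral", "initial_macroalgae"]].to_numpy(dtype=float)
    if np.any(cov < 0) or np.any(cov > 1):
        bad = reefs.loc[np.any((cov < 0) | (cov > 1), axis=1), "reef_id"].iloc[0]
        raise ReefTableValidationError(f"cover outside [0, 1] at reef_id {bad!r}")
    sums = cov.sum(axis=1)
    if np.any(sums > 1.0 + 1e-12):
        bad = reefs.loc[sums > 1.0 + 1e-12, "reef_id"].iloc[0]
        raise ReefTableValidationError(
            f"initial_coral + initial_macroalgae > 1 at reef_id {bad!r}"
        )


def generate_seascape(
    n_reefs: int = 75,
    n_grounds: int = 8,
    closure_fraction: float = 21.0 / 75.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic reef table: clustered coordinates, closures,
    skewed herbivore densities, coast-decaying sediment and benthic covers.

    ``round(n_reefs * closure_fraction)`` reefs are placed in fishery
    closures, each as the single original reef of its own closure.
    Deterministic given ``seed``.
    """
    if n_reefs < 2 or n_grounds < 1:
        raise ValueError("n_reefs must be >= 2 and n_grounds >= 1")
    if not 0.0 <= closure_fraction <= 1.0:
        raise ValueError("closure_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    ground_lon = rng.uniform(*_LON_RANGE, n_grounds)
    ground_lat = rng.uniform(*_LAT_RANGE, n_grounds)
    ground = rng.integers(0, n_grounds, n_reefs)
    lon = ground_lon[ground] + rng.normal(0.0, _REEF_SCATTER_DEG, n_reefs)
    lat = np.clip(
        ground_lat[ground] + rng.normal(0.0, _REEF_SCATTER_DEG, n_reefs),
        -89.9, 89.9,
    )

    n_closed = int(round(n_reefs * closure_fraction))
    closed = rng.choice(n_reefs, size=n_closed, replace=False)
    closure_id = np.array([None] * n_reefs, dtype=object)
    for rank, idx in enumerate(sorted(closed), start=1):
        closure_id[idx] = f"tabu{rank:02d}"

    density = rng.lognormal(np.log(_DENSITY_MEDIAN), _DENSITY_SDLOG, n_reefs)
    coast_km = (lat - _COAST_LAT) * 111.195  # offshore distance to the coast axis
    sediment = (
        _SEDIMENT_SCALE
        * np.exp(-np.maximum(coast_km, 0.0) / _SEDIMENT_DECAY_KM)
        * rng.lognormal(0.0, _SEDIMENT_NOISE_SD, n_reefs)
    )

    coral = rng.beta(1.7, 4.0, n_reefs)
    macro = rng.beta(1.2, 6.0, n_reefs) * (1.0 - coral)

    reefs = pd.DataFrame(
        {
            "reef_id": np.arange(1, n_reefs + 1),
            "lon": lon,
            "lat": lat,
            "fishing_ground": np.array([f"qoliqoli{g + 1:02d}" for g in ground]),
            "closure_id": closure_id,
            "herbivore_density": density,
            "sediment_index": sediment,
            "initial_coral": coral,
            "initial_macroalgae": macro,
        }
    )
    validate_reef_table(reefs)
    return reefs


def generate_connectivity(
    reefs: pd.DataFrame,
    pld_days: float,
    kernel: KernelConfig | None = None,
    seed: int = 0,
    kind: str = "coral",
) -> ConnectivityMatrix:
    """Distance-decay connectivity for the given PLD; deterministic given seed.

    Entries are ``p0 * exp(-dist/lambda)`` with ``lambda = speed * pld_days``,
    roughened by lognormal noise if ``noise_sd > 0``, pruned below
    ``prune_threshold`` and clipped to [0, 1].
    """
    if len(reefs) == 0:
        raise ValueError("reef table is empty")
    if pld_days <= 0:
        raise ValueError("pld_days must be positive")
    kernel = kernel or KernelConfig()
    dist = pairwise_distance_km(reefs["lon"].to_numpy(), reefs["lat"].to_numpy())
    lam = kernel.speed_km_per_day * float(pld_days)
    values = kernel.p0 * np.exp(-dist / lam)
    if kernel.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * rng.lognormal(0.0, kernel.noise_sd, values.shape)
    values[values < kernel.prune_threshold] = 0.0
    values = np.clip(values, 0.0, 1.0)
    return ConnectivityMatrix(values, reefs["reef_id"].to_numpy(), kind, float(pld_days))


def weighted_average_connectivity(
    matrices: Sequence[ConnectivityMatrix],
    weights: Sequence[float] | None = None,
) -> ConnectivityMatrix:
    """Element-wise convex combination of same-shape matrices.

    Weights are normalized to sum to one; the result carries the
    ``weighted-average`` PLD marker.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    if weights is None:
        weights = np.ones(len(matrices))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(matrices) or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per matrix")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("all matrices must share the same shape")
        if not np.array_equal(m.reef_ids, first.reef_ids):
            raise ValueError("all matrices must share the same reef order")
        if m.kind != first.kind:
            raise ValueError("all matrices must share the same kind")
    w = weights / total
    values = sum(wi * m.values for wi, m in zip(w, matrices))
    return ConnectivityMatrix(values, first.reef_ids.copy(), first.kind, WEIGHTED_AVERAGE)


#: Uniform cover levels of the stylized initial-condition scenarios.
IC_HIGH = 0.75
IC_LOW = 0.05

IC_SCENARIOS = ("empirical", "very_high_coral", "very_low_coral")


def generate_initial_conditions(
    reefs: pd.DataFrame,
    scenario: str = "empirical",
    high: float = IC_HIGH,
    low: float = IC_LOW,
) -> StateVector:
    """Initial (M, C) per reef for a named scenario.

    "empirical" reads the table's covers; "very_high_coral" sets every reef to
    (M=low, C=high); "very_low_coral" swaps the two.
    """
    if scenario not in IC_SCENARIOS:
        raise ValueError(f"unknown initial-condition scenario {scenario!r}")
    n = len(reefs)
    if scenario == "empirical":
        return StateVector(
            reefs["initial_macroalgae"].to_numpy(dtype=float),
            reefs["initial_coral"].to_numpy(dtype=float),
        )
    if high + low > 1.0:
        raise ValueError("scenario covers must sum to at most 1")
    if scenario == "very_high_coral":
        return StateVector.uniform(n, M=low, C=high)
    return StateVector.uniform(n, M=high, C=low)
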