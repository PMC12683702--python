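"""Translate reef covariates into dynamical rates under a named grazing scenario.

Herbivore biomass density (kg/ha) becomes a per-reef grazing rate g_i by
multiplication with a consumption-rate constant chosen so that the network
median equals the scenario's target (0.1 / 0.3 / 0.5 for low / medium / high).
Sediment exposure becomes a per-reef coral mortality rate d_i by a
rank-preserving affine rescale centred on a target median mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_A, DEFAULT_D_MED, DEFAULT_GAMMA, DEFAULT_R, SystemParams
from .seascape import ConnectivityMatrix, validate_reef_table

#: Scenario name -> network median grazing rate.
SCENARIO_MEDIANS = {"low": 0.1, "medium": 0.3, "high": 0.5}


@dataclass(frozen=True)
class GrazingScenario:
    name: str
    g_median: float

    def __post_init__(self):
        if self.name in SCENARIO_MEDIANS and SCENARIO_MEDIANS[self.name] != self.g_median:
            raise ValueError(
                f"scenario {self.name!r} must have g_median {SCENARIO_MEDIANS[self.name]}"
            )
        if self.g_median <= 0:
            raise ValueError("g_median must be positive")

    @classmethod
    def from_name(cls, name: str) -> "GrazingScenario":
        if name not in SCENARIO_MEDIANS:
            raise ValueError(f"unknown grazing scenario {name!r}")
        return cls(name, SCENARIO_MEDIANS[name])


@dataclass(frozen=True)
class MortalityConfig:
    """Target median coral mortality and the half-width factor of the rescaled
    range: d values span at most [d_med*(1-spread), d_med*(1+spread)]."""

    d_med: float = DEFAULT_D_MED
    spread: float = 0.5

    def __post_init__(self):
        if self.d_med <= 0:
            raise ValueError("d_med must be positive")
        if not 0.0 <= self.spread < 1.0:
            raise ValueError("spread must lie in [0, 1)")


def _as_scenario(scenario: GrazingScenario | str) -> GrazingScenario:
    if isinstance(scenario, str):
        return GrazingScenario.from_name(scenario)
    return scenario


def grazing_from_density(
    density: np.ndarray, scenario: GrazingScenario | str
) -> np.ndarray:
    """g_i = c * density_i with c fixed so that median(g) equals the scenario
    median exactly. Zero-density reefs keep g = 0."""
    scenario = _as_scenario(scenario)
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("densities must be non-negative")
    med = np.median(density)
    if med <= 0:
        raise ValueError(
            "median herbivore density is zero; grazing cannot be scaled"
        )
    return scenario.g_median / med * density


def mortality_from_sediment(
    sediment: np.ndarray, cfg: MortalityConfig | None = None
) -> np.ndarray:
    """Rank-preserving affine rescale of sediment onto a mortality band centred
    at d_med.

    d_i = d_med + k * (s_i - median(s)) with a single slope k =
    min(spread*d_med / (max-median), spread*d_med / (median-min)), so the
    median maps to d_med exactly (for even-length inputs too) and no value
    leaves [d_med*(1-spread), d_med*(1+spread)]. Constant input maps to d_med.
    """
    cfg = cfg or MortalityConfig()
    sediment = np.asarray(sediment, dtype=float)
    if np.any(sediment < 0):
        raise ValueError("sediment indices must be non-negative")
    med = np.median(sediment)
    half = cfg.spread * cfg.d_med
    slopes = [
        half / (sediment.max() - med) if sediment.max() > med else np.inf,
        half / (med - sediment.min()) if med > sediment.min() else np.inf,
    ]
    k = min(slopes)
    if not np.isfinite(k):  # constant input
        return np.full(sediment.shape, cfg.d_med)
    return cfg.d_med + k * (sediment - med)


def build_system(
    reefs: pd.DataFrame,
    K: ConnectivityMatrix,
    N: ConnectivityMatrix,
    scenario: GrazingScenario | str,
    mort_cfg: MortalityConfig | None = None,
    a: float = DEFAULT_A,
    r: float = DEFAULT_R,
    gamma: float = DEFAULT_GAMMA,
) -> SystemParams:
    """Assemble the full dynamical system for a reef table and its matrices.

    The matrices must list reef ids in exactly the table's order; a mismatch
    is an error rather than a silent reorder.
    """
    validate_reef_table(reefs)
    scenario = _as_scenario(scenario)
    ids = reefs["reef_id"].to_numpy()
    for name, m in (("K", K), ("N", N)):
        if not np.array_equal(m.reef_ids, ids):
            raise ValueError(f"{name} reef order does not match the reef table")
    g = grazing_from_density(reefs["herbivore_density"].to_numpy(), scenario)
    d = mortality_from_sediment(reefs["sediment_index"].to_numpy(), mort_cfg)
    return SystemParams(
        g=g, d=d, a=a, r=r, gamma=gamma,
        K=K.values, N=N.values, scenario=scenario.name,
    )
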