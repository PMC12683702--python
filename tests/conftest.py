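import numpy as np
import pandas as pd
import pytest

import reefnet as rn


@pytest.fixture(scope="session")
def reefs10():
    return rn.generate_seascape(n_reefs=10, n_grounds=2, closure_fraction=0.3, seed=42)


@pytest.fixture(scope="session")
def reefs75():
    return rn.generate_seascape(n_reefs=75, n_grounds=8, closure_fraction=21 / 75, seed=1)


def make_random_system(seed: int, n: int = 5) -> tuple[rn.SystemParams, rn.StateVector]:
    """Random but valid n-reef system: heterogeneous rates, mixed connectivity."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.6, n)
    d = rng.uniform(0.2, 0.6, n)
    K = rng.uniform(0.0, 0.2, (n, n))
    np.fill_diagonal(K, rng.uniform(0.4, 0.9, n))
    N = rng.uniform(0.0, 0.1, (n, n))
    np.fill_diagonal(N, rng.uniform(0.4, 0.9, n))
    params = rn.SystemParams(g=g, d=d, a=0.1, r=1.0, gamma=0.8, K=K, N=N)
    M0 = rng.uniform(0.0, 0.5, n)
    C0 = np.minimum(rng.uniform(0.0, 0.5, n), 1.0 - M0)
    return params, rn.StateVector(M0, C0)


@pytest.fixture()
def random_system():
    return make_random_system


def collinear_reefs(offsets_km, closure_flags, grounds=None) -> pd.DataFrame:
    """Reefs along the equator at given eastward offsets (km)."""
    n = len(offsets_km)
    grounds = grounds or ["q1"] * n
    deg_per_km = 1.0 / 111.19492664455873
    return pd.DataFrame(
        {
            "reef_id": np.arange(1, n + 1),
            "lon": np.asarray(offsets_km, dtype=float) * deg_per_km,
            "lat": np.zeros(n),
            "fishing_ground": grounds,
            "closure_id": [f"c{i}" if f else None for i, f in enumerate(closure_flags)],
            "herbivore_density": np.full(n, 100.0),
            "sediment_index": np.full(n, 1.0),
            "initial_coral": np.full(n, 0.3),
            "initial_macroalgae": np.full(n, 0.2),
        }
    )
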