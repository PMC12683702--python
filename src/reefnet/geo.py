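"""Great-circle geometry helpers shared by the seascape generator and management rules."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lat2 = np.radians(lat1), np.radians(lat2)
    dlat = lat2 - lat1
    dlon = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards round-off for antipodal / identical points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distance_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Symmetric pairwise haversine distance matrix (km) with zero diagonal."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitudes must lie in [-90, 90]")
    d = haversine_km(lon[None, :], lat[None, :], lon[:, None], lat[:, None])
    np.fill_diagonal(d, 0.0)
    return d
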