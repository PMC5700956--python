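"""Pairwise dissimilarity matrices: Bray-Curtis, elevation differences,
group membership, and geographic distance (planar or haversine).

No abundance pre-transformation is applied before Bray-Curtis: the metric
is computed directly on presence/absence or raw counts, so nothing happens
behind the caller's back.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CommunityMatrix, DistanceMatrix, SiteTable, ValidationError

__all__ = [
    "bray_curtis",
    "euclidean_1d",
    "membership_distance",
    "geographic_distance",
    "write_distance_matrix",
    "read_distance_matrix",
]

EARTH_RADIUS_KM = 6371.0


def bray_curtis(comm: CommunityMatrix, use_presence: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = sum|x_i - x_j| / sum(x_i + x_j).

    On presence/absence data this equals the Sorensen dissimilarity.
    """
    X = (comm.presence if use_presence else comm.data).to_numpy(dtype=float)
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    if empty.size:
        names = [comm.sites[i] for i in empty]
        raise ValidationError(f"sites with all-zero rows (Bray-Curtis undefined): {names}")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    kind = "presence" if use_presence else "abundance"
    return DistanceMatrix(comm.sites, num / den, name=f"bray_curtis_{kind}")


def euclidean_1d(values: pd.Series, name: str = "euclidean_1d") -> DistanceMatrix:
    """Pairwise absolute differences of one scalar per site (e.g. elevation)."""
    v = pd.Series(values).astype(float)
    bad = v.index[v.isna()].tolist()
    if bad:
        raise ValidationError(f"missing values for sites: {bad}")
    arr = v.to_numpy()
    return DistanceMatrix(list(v.index), np.abs(arr[:, None] - arr[None, :]), name=name)


def membership_distance(labels: pd.Series, name: str = "membership") -> DistanceMatrix:
    """Binary distance: 0 if two sites share the label, 1 otherwise."""
    s = pd.Series(labels)
    bad = s.index[s.isna()].tolist()
    if bad:
        raise ValidationError(f"missing labels for sites: {bad}")
    arr = s.to_numpy()
    vals = (arr[:, None] != arr[None, :]).astype(float)
    return DistanceMatrix(list(s.index), vals, name=name)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) on a sphere of mean Earth radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distance(sites: SiteTable) -> DistanceMatrix:
    """Pairwise geographic distance in km.

    Planar coordinates use Euclidean distance; lon/lat use the haversine
    formula. Mixed systems are impossible by construction (one flag per table).
    """
    x = sites.data["x"].to_numpy(dtype=float)
    y = sites.data["y"].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        bad = [sid for sid, xx, yy in zip(sites.site_ids, x, y)
               if np.isnan(xx) or np.isnan(yy)]
        raise ValidationError(f"missing coordinates for sites: {bad}")
    if sites.coord_system == "planar":
        vals = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    else:
        vals = haversine_km(x[:, None], y[:, None], x[None, :], y[None, :])
    return DistanceMatrix(sites.site_ids, vals, name=f"geographic_{sites.coord_system}")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square labelled CSV, 12 significant digits (round-trip exact at that precision)."""
    df = dm.to_frame()
    df.to_csv(path, float_format="%.12g")


def read_distance_matrix(path, name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix file must have matching row/column labels")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), name=name)
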