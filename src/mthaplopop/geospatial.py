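"""Spatial interpolation and autocorrelation of haplogroup frequencies.

Inverse-distance-weighted (IDW) interpolation draws a frequency surface
over a lat/lon grid from point observations, assuming each input point has
a local influence that decreases with distance (power 2 by default).
Moran's I measures spatial autocorrelation of the point values; a
correlogram evaluates it per geographic distance class (14 equal-count
classes by default) with permutation significance.  A cline -- a monotone
geographic gradient -- is diagnosed from a correlogram that starts positive
and significant and declines with distance.

Distances are great-circle (haversine) kilometres on a sphere of radius
6371 km; no map projection is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "IDWConfig",
    "FrequencySurface",
    "CorrelogramClass",
    "Correlogram",
    "greatcircle_distance",
    "pairwise_distances",
    "idw_interpolate",
    "morans_i",
    "correlogram",
    "detect_cline",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A population sample location with one frequency value in [0, 1]."""

    population: str
    lat: float
    lon: float
    value: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"frequency {self.value} outside [0, 1]")


def greatcircle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance in kilometres."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_distances(points: Sequence[GeoPoint]) -> np.ndarray:
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = greatcircle_distance(points[i], points[j])
    return d


@dataclass(frozen=True)
class IDWConfig:
    """Inverse-distance-weighting settings.

    ``power`` is the distance exponent (2 is the conventional default);
    the grid is a regular lat/lon lattice over the bounding box with the
    given cell size in degrees.  ``max_neighbors`` restricts interpolation
    to the closest points when set.
    """

    power: float = 2.0
    lat_min: float = -35.0
    lat_max: float = 40.0
    lon_min: float = -20.0
    lon_max: float = 60.0
    cell_size_deg: float = 1.0
    max_neighbors: int | None = None

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")


@dataclass(frozen=True)
class FrequencySurface:
    """A gridded interpolated surface: values[i, j] at (lats[i], lons[j])."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def to_frame(self):
        """Long-format DataFrame (lat, lon, value)."""
        import pandas as pd

        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        return pd.DataFrame(
            {"lat": la.ravel(), "lon": lo.ravel(), "value": self.values.ravel()}
        )


def idw_interpolate(points: Sequence[GeoPoint], cfg: IDWConfig | None = None) -> FrequencySurface:
    """Inverse-distance-weighted surface of the point values.

    ``z(x) = sum_i d_i^-p z_i / sum_i d_i^-p``; a grid node coincident with
    a sample takes that sample's value exactly, and every interpolated value
    lies within [min z, max z].
    """
    if not points:
        raise ValueError("need at least one point")
    cfg = cfg or IDWConfig()
    lats = np.arange(cfg.lat_min, cfg.lat_max + 1e-9, cfg.cell_size_deg)
    lons = np.arange(cfg.lon_min, cfg.lon_max + 1e-9, cfg.cell_size_deg)
    z = np.array([p.value for p in points])
    values = np.empty((lats.size, lons.size))
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            node = GeoPoint("grid", float(la), float(lo), 0.0)
            d = np.array([greatcircle_distance(node, p) for p in points])
            hit = np.where(d < 1e-9)[0]
            if hit.size:
                values[i, j] = z[hit[0]]
                continue
            if cfg.max_neighbors is not None and cfg.max_neighbors < d.size:
                idx = np.argsort(d)[: cfg.max_neighbors]
                w = d[idx] ** -cfg.power
                values[i, j] = float(np.dot(w, z[idx]) / w.sum())
            else:
                w = d**-cfg.power
                values[i, j] = float(np.dot(w, z) / w.sum())
    return FrequencySurface(lats=lats, lons=lons, values=values)


def morans_i(values: Sequence[float], weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation coefficient.

    ``I = (n/W) sum_ij w_ij (z_i - mean)(z_j - mean) / sum_i (z_i - mean)^2``
    for a symmetric zero-diagonal weight matrix with total weight W.
    Returns NaN when the values have zero variance (undefined).
    """
    z = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 points")
    if w.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    W = w.sum()
    if W <= 0:
        raise ValueError("weight matrix has no nonzero weights")
    dz = z - z.mean()
    denom = float(np.dot(dz, dz))
    if denom == 0.0:
        return math.nan
    return float(n / W * dz @ w @ dz / denom)


@dataclass(frozen=True)
class CorrelogramClass:
    """One distance class of a correlogram."""

    lower_km: float
    upper_km: float
    mean_distance_km: float
    n_pairs: int
    morans_i: float
    p_value: float


@dataclass(frozen=True)
class Correlogram:
    classes: tuple[CorrelogramClass, ...]
    n_points: int
    reps: int

    @property
    def expected_i(self) -> float:
        """Null expectation of Moran's I, -1/(n-1)."""
        return -1.0 / (self.n_points - 1)


def _equal_count_edges(d_flat: np.ndarray, n_classes: int) -> list[np.ndarray]:
    """Partition pair indices into n_classes rank-contiguous chunks.

    Rank-based chunking guarantees every pair falls in exactly one class
    even with tied distances; class sizes differ by at most one.
    """
    order = np.argsort(d_flat, kind="stable")
    return [chunk for chunk in np.array_split(order, n_classes)]


def correlogram(
    points: Sequence[GeoPoint],
    n_classes: int = 14,
    reps: int = 999,
    seed: int | np.random.Generator = 0,
) -> Correlogram:
    """Moran's I correlogram over equal-count geographic distance classes.

    For each class, a binary weight matrix selects the point pairs whose
    separation falls in the class, and significance is assessed by
    permuting the values over locations (two-sided around the null
    expectation -1/(n-1)).  Deterministic under a fixed seed.
    """
    n = len(points)
    n_pairs = n * (n - 1) // 2
    if n_pairs < n_classes:
        import warnings

        warnings.warn(
            f"only {n_pairs} pairs for {n_classes} classes; reducing",
            stacklevel=2,
        )
        n_classes = max(1, n_pairs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = pairwise_distances(points)
    iu = np.triu_indices(n, k=1)
    d_flat = d[iu]
    z = np.array([p.value for p in points])
    e_i = -1.0 / (n - 1)

    # permutations shared across classes: permute values once per rep
    perms = [rng.permutation(n) for _ in range(reps)]
    classes = []
    for chunk in _equal_count_edges(d_flat, n_classes):
        w = np.zeros((n, n))
        rows, cols = iu[0][chunk], iu[1][chunk]
        w[rows, cols] = w[cols, rows] = 1.0
        i_obs = morans_i(z, w)
        if math.isnan(i_obs):
            p = math.nan
        else:
            null = np.array([morans_i(z[pm], w) for pm in perms])
            p = float((np.sum(np.abs(null - e_i) >= abs(i_obs - e_i)) + 1) / (reps + 1))
        classes.append(
            CorrelogramClass(
                lower_km=float(d_flat[chunk].min()),
                upper_km=float(d_flat[chunk].max()),
                mean_distance_km=float(d_flat[chunk].mean()),
                n_pairs=int(chunk.size),
                morans_i=i_obs,
                p_value=p,
            )
        )
    return Correlogram(classes=tuple(classes), n_points=n, reps=reps)


def detect_cline(
    c: Correlogram,
    alpha: float = 0.05,
    require_negative_tail: bool = True,
    tail_classes: int = 3,
) -> bool:
    """Diagnose a geographic cline from a correlogram.

    True when (i) the shortest-distance class has positive, significant
    Moran's I; (ii) I declines with distance class (negative Spearman rank
    correlation, p < alpha); and (iii) at least one of the last
    ``tail_classes`` classes has negative I (optional).  Undefined
    (zero-variance) correlograms are never clines.
    """
    ivals = [cl.morans_i for cl in c.classes]
    if any(math.isnan(v) for v in ivals):
        return False
    first = c.classes[0]
    if not (first.morans_i > 0 and first.p_value < alpha):
        return False
    rho_s, p_s = stats.spearmanr(range(len(ivals)), ivals)
    if not (rho_s < 0 and p_s < alpha):
        return False
    if require_negative_tail:
        tail = ivals[-tail_classes:]
        if not any(v < 0 for v in tail):
            return False
    return True
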