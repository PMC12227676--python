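"""Per-participant location representations.

Three encodings of a GPS fix's whereabouts are supported, mirroring the
three ways stay regions are commonly summarised in mobile-health work:

* **DBSCAN** — density-based clusters over great-circle distances;
  sparse points become an explicit noise category (label -1). Cluster
  ids are renumbered in order of first appearance so results are
  deterministic.
* **K-means** — run on locally projected planar coordinates with the
  number of clusters chosen automatically by the silhouette score.
* **DFI** (distance from initial) — great-circle metres from the
  participant's first recorded fix, a simple mobility proxy.

All three are translation-invariant, so they commute with the constant
privacy offset applied to published coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6371008.8

METHOD_DBSCAN = "dbscan"
METHOD_KMEANS = "kmeans"
METHOD_DFI = "dfi"
METHODS = (METHOD_DBSCAN, METHOD_KMEANS, METHOD_DFI)


@dataclass
class SpatialConfig:
    method: str = METHOD_DBSCAN
    eps_m: float = 100.0
    min_samples: int = 5
    k_range: tuple[int, int] = (2, 10)
    distance_model: str = "haversine"  # or "equirectangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}")
        if self.eps_m <= 0:
            raise ConfigError("eps_m must be > 0")
        if self.min_samples < 1:
            raise ConfigError("min_samples must be >= 1")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ConfigError("k_range must satisfy 2 <= lo <= hi")
        if self.distance_model not in ("haversine", "equirectangular"):
            raise ConfigError("distance_model must be haversine or equirectangular")


@dataclass
class SpatialRepresentation:
    """Per-fix location value: cluster labels or metres from the anchor."""

    method: str
    values: np.ndarray  # int labels (DBSCAN/K-means) or float metres (DFI)
    chosen_k: int | None = None

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _check_coords(lat, lon) -> tuple[np.ndarray, np.ndarray]:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("coordinates outside WGS84 bounds")
    return lat, lon


def great_circle_distance(p1, p2, distance_model: str = "haversine") -> np.ndarray:
    """Distance in metres between WGS84 points (broadcasting over arrays)."""
    lat1, lon1 = _check_coords(p1[0], p1[1])
    lat2, lon2 = _check_coords(p2[0], p2[1])
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2) - np.radians(lon1)
    if distance_model == "haversine":
        a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
        return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    x = dlmb * np.cos((phi1 + phi2) / 2)
    return EARTH_RADIUS_M * np.hypot(dphi, x)


def project_equirectangular(lat, lon) -> np.ndarray:
    """Project coordinates to planar metres about their centroid."""
    lat, lon = _check_coords(lat, lon)
    lat0, lon0 = lat.mean(), lon.mean()
    x = np.radians(lon - lon0) * math.cos(math.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _first_appearance_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids in order of first appearance; noise stays -1."""
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lb in enumerate(labels):
        if lb == -1:
            continue
        if lb not in mapping:
            mapping[lb] = len(mapping)
        out[i] = mapping[lb]
    return out


def dbscan_clusters(lat, lon, config: SpatialConfig | None = None) -> SpatialRepresentation:
    """DBSCAN over great-circle distances; -1 marks noise points."""
    config = config or SpatialConfig()
    lat, lon = _check_coords(lat, lon)
    if len(lat) < 1:
        raise ValidationError("dbscan_clusters requires at least one fix")
    X = np.radians(np.column_stack([lat, lon]))
    model = DBSCAN(eps=config.eps_m / EARTH_RADIUS_M,
                   min_samples=config.min_samples, metric="haversine")
    labels = model.fit_predict(X)
    return SpatialRepresentation(METHOD_DBSCAN,
                                 _first_appearance_relabel(labels))


def silhouette_select_k(lat, lon, k_range=(2, 10), seed: int = 0) -> int:
    """Pick the K-means cluster count maximising the mean silhouette.

    Candidates with fewer distinct points than clusters are skipped; ties
    go to the smaller k. With fewer than 3 distinct points no candidate
    is feasible and the sentinel k=1 (single cluster) is returned.
    """
    lat, lon = _check_coords(lat, lon)
    if len(lat) == 0:
        raise ValidationError("silhouette_select_k requires fixes")
    X = project_equirectangular(lat, lon)
    n_distinct = len(np.unique(X, axis=0))
    best_k, best_s = None, -np.inf
    for k in range(k_range[0], k_range[1] + 1):
        if k >= n_distinct or k > len(X) - 1:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1e-12:  # strict improvement: ties keep smaller k
            best_k, best_s = k, s
    if best_k is None:
        logger.warning("no feasible k in %s; falling back to a single cluster",
                       k_range)
        return 1
    return best_k


def kmeans_clusters(lat, lon, config: SpatialConfig | None = None) -> SpatialRepresentation:
    """K-means on projected planar coordinates with silhouette-chosen k."""
    config = config or SpatialConfig(method=METHOD_KMEANS)
    lat, lon = _check_coords(lat, lon)
    if len(lat) < 1:
        raise ValidationError("kmeans_clusters requires at least one fix")
    k = silhouette_select_k(lat, lon, config.k_range, config.seed)
    if k == 1:
        return SpatialRepresentation(METHOD_KMEANS,
                                     np.zeros(len(lat), dtype=int), chosen_k=1)
    X = project_equirectangular(lat, lon)
    km = KMeans(n_clusters=k, n_init=10, random_state=config.seed)
    labels = km.fit_predict(X)
    return SpatialRepresentation(METHOD_KMEANS,
                                 _first_appearance_relabel(labels), chosen_k=k)


def distance_from_initial(lat, lon, distance_model: str = "haversine") -> SpatialRepresentation:
    """Metres from the participant's first recorded fix (fixes time-sorted)."""
    lat, lon = _check_coords(lat, lon)
    if len(lat) == 0:
        raise ValidationError("distance_from_initial requires fixes")
    d = great_circle_distance((np.full_like(lat, lat[0]),
                               np.full_like(lon, lon[0])),
                              (lat, lon), distance_model)
    return SpatialRepresentation(METHOD_DFI, np.asarray(d, dtype=float))


def compute_representation(lat, lon, config: SpatialConfig) -> SpatialRepresentation:
    """Dispatch to the configured location representation."""
    if config.method == METHOD_DBSCAN:
        return dbscan_clusters(lat, lon, config)
    if config.method == METHOD_KMEANS:
        return kmeans_clusters(lat, lon, config)
    return distance_from_initial(lat, lon, config.distance_model)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_location_feature(representation: SpatialRepresentation,
                            row_fix_idx=None) -> tuple[np.ndarray, list[str]]:
    """Turn a representation into model-ready feature columns.

    Cluster labels become a one-hot block (noise gets its own column);
    DFI becomes a single z-scored numeric column (zeros when the stream
    has no variance). ``row_fix_idx`` maps sample-table rows to fixes so
    fallback rows inherit the encoding of their source fix.
    """
    vals = representation.values
    if row_fix_idx is not None:
        vals = vals[np.asarray(row_fix_idx, dtype=int)]
    if representation.method == METHOD_DFI:
        sd = vals.std()
        col = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        return col.reshape(-1, 1), ["dfi_z"]
    labels = sorted(set(int(v) for v in representation.values))
    cols = []
    names = []
    for lb in labels:
        cols.append((vals == lb).astype(float))
        names.append("loc_noise" if lb == -1 else f"loc_{lb}")
    return np.column_stack(cols), names
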