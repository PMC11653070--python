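"""Habitat reclassification, class areas, natural-breaks classing, and
centroid-migration vectors between periods or climate scenarios.

Suitability surfaces (0-1) are cut into four classes — unsuitable,
secondarily suitable, suitable, optimal — at fixed edges (0.1, 0.25, 0.5].
Class areas use true spherical cell areas, and the "centre of mass" of the
suitable range is tracked between periods as a great-circle displacement
(distance + initial bearing, plus an 8-sector compass label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import EARTH_RADIUS_KM, RasterLayer, cell_areas
from .occurrences import haversine_km

CLASS_NAMES = ("unsuitable", "secondary", "suitable", "optimal")
DEFAULT_EDGES = (0.1, 0.25, 0.5)
COMPASS_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class HabitatClassMap:
    layer: RasterLayer            # integer codes 0..3, nodata preserved
    edges: tuple[float, ...]
    class_names: tuple[str, ...] = CLASS_NAMES

    def class_mask(self, name: str) -> np.ndarray:
        code = self.class_names.index(name)
        return self.layer.mask & (self.layer.values == code)


@dataclass
class Centroid:
    lon: float
    lat: float
    weighting: str = "suitability_weighted"


@dataclass
class MigrationVector:
    start: Centroid
    end: Centroid
    distance_km: float
    bearing_deg: float

    @property
    def sector(self) -> str:
        return COMPASS_SECTORS[int(((self.bearing_deg + 22.5) % 360) // 45)]


def reclassify_fixed(suitability: RasterLayer,
                     edges: tuple[float, float, float] = DEFAULT_EDGES
                     ) -> HabitatClassMap:
    """Cut a 0-1 suitability surface into the four habitat classes.

    Bins are (0, e1] unsuitable, (e1, e2] secondary, (e2, e3] suitable,
    (e3, 1] optimal — contiguous edges so every valid cell is classified.
    """
    if not (edges[0] < edges[1] < edges[2]):
        raise ValueError(f"edges must be strictly increasing, got {edges}")
    m = suitability.mask
    v = suitability.values
    if np.any((v[m] < 0) | (v[m] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.digitize(v, edges, right=True).astype(float)
    codes = np.where(m, codes, suitability.spec.nodata)
    return HabitatClassMap(RasterLayer(suitability.spec, "habitat_class", codes),
                           tuple(edges))


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Jenks natural breaks by dynamic programming.

    Returns the k-1 interior break values (upper bound of each class but the
    last), minimizing total within-class sum of squared deviations.
    """
    if k < 2:
        raise ValueError("need at least 2 classes")
    x = np.sort(np.asarray(values, float).ravel())
    n = x.size
    if len(np.unique(x)) < k:
        raise ValueError(f"need >= {k} distinct values, got {len(np.unique(x))}")
    # prefix sums for O(1) within-class SSD of x[i:j]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    prev = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            cnt = j - i
            s = cs[j] - cs[i]
            s2 = cs2[j] - cs2[i]
            vals = cost[c - 1, i] + (s2 - s * s / cnt)
            arg = int(np.argmin(vals))
            cost[c, j] = vals[arg]
            prev[c, j] = i[arg]
    # recover class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = prev[c, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # interior split indices
    return [float(x[b - 1]) for b in bounds]


def class_areas(classmap: HabitatClassMap, areas: RasterLayer | None = None
                ) -> dict[str, float]:
    """Total spherical area (km²) per habitat class."""
    layer = classmap.layer
    if areas is None:
        areas = cell_areas(layer.spec)
    elif not areas.spec.same_geometry(layer.spec):
        raise ValueError("area layer is on a different grid")
    m = layer.mask
    out = {}
    for code, name in enumerate(classmap.class_names):
        out[name] = float(areas.values[m & (layer.values == code)].sum())
    return out


def centroid(suitability: RasterLayer, mode: str = "suitability_weighted",
             threshold: float = 0.25,
             classmap: HabitatClassMap | None = None,
             classes: tuple[str, ...] = ("suitable", "optimal"),
             areas: RasterLayer | None = None) -> Centroid:
    """Area-weighted centre of mass of the suitable range.

    mode='suitability_weighted': weights = suitability * cell area over cells
    with suitability >= threshold.  mode='binary_class': weights = cell area
    over member cells of the given classes of ``classmap``.
    """
    spec = suitability.spec
    if areas is None:
        areas = cell_areas(spec)
    if mode == "suitability_weighted":
        m = suitability.mask & (suitability.values >= threshold)
        w = suitability.values * areas.values
    elif mode == "binary_class":
        if classmap is None:
            raise ValueError("binary_class mode requires a classmap")
        m = np.zeros(suitability.values.shape, bool)
        for c in classes:
            m |= classmap.class_mask(c)
        w = areas.values
    else:
        raise ValueError(f"unknown centroid mode {mode!r}")
    if not m.any() or w[m].sum() <= 0:
        raise ValueError("zero weight mass; centroid undefined")
    lon2d, lat2d = np.meshgrid(spec.lon_centers(), spec.lat_centers())
    wt = w[m]
    return Centroid(float((lon2d[m] * wt).sum() / wt.sum()),
                    float((lat2d[m] * wt).sum() / wt.sum()),
                    weighting=mode)


def _initial_bearing(lon1, lat1, lon2, lat2) -> float:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(y, x)) % 360)


def migration(start: Centroid, end: Centroid) -> MigrationVector:
    """Great-circle displacement between two centroids (km, bearing with
    0 = north, clockwise)."""
    d = float(haversine_km(start.lon, start.lat, end.lon, end.lat))
    if d == 0.0:
        return MigrationVector(start, end, 0.0, 0.0)
    return MigrationVector(start, end, d,
                           _initial_bearing(start.lon, start.lat, end.lon, end.lat))
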