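"""Occurrence ingest, deduplication, spatial thinning and train/test splits.

Presence records are lon/lat points.  Spatial thinning enforces a minimum
pairwise great-circle distance (the classic 10-km rule used to reduce
sampling bias in herbarium data) with a seeded randomized-greedy rule so the
result is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    source_tag: str = ""

    def __post_init__(self):
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass
class OccurrenceSet:
    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records])

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records])

    def coords(self) -> np.ndarray:
        return np.column_stack([self.lons, self.lats]) if self.records else \
            np.empty((0, 2))

    def dedupe(self) -> "OccurrenceSet":
        """Drop exact duplicate (lon, lat) pairs, keeping first occurrence."""
        seen, out = set(), []
        for r in self.records:
            key = (r.lon, r.lat)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return OccurrenceSet(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": self.lons, "lat": self.lats,
             "source_tag": [r.source_tag for r in self.records]}
        )


def read_occurrences(path, lon_col: str = "lon", lat_col: str = "lat",
                     tag_col: str = "source_tag") -> OccurrenceSet:
    """Read presence points from CSV, rejecting out-of-range rows.

    Invalid rows are dropped with a row-numbered warning rather than aborting
    the run; a missing lon/lat column is a schema error.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        warnings.warn(f"{path}: empty occurrence file")
        return OccurrenceSet([])
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}' "
                             f"(found {list(df.columns)})")
    records, rejected = [], []
    for i, row in df.iterrows():
        try:
            lon, lat = float(row[lon_col]), float(row[lat_col])
            tag = str(row[tag_col]) if tag_col in df.columns else ""
            records.append(OccurrenceRecord(lon, lat, tag))
        except (ValueError, TypeError) as e:
            rejected.append((i + 2, str(e)))  # +2: header + 1-based
    if rejected:
        msgs = "; ".join(f"row {n}: {m}" for n, m in rejected[:5])
        warnings.warn(f"{path}: rejected {len(rejected)} invalid rows ({msgs})")
    return OccurrenceSet(records)


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.to_frame().to_csv(path, index=False)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin(occ: OccurrenceSet, min_km: float, seed: int = 0) -> OccurrenceSet:
    """Randomized-greedy spatial thinning to a minimum pairwise distance.

    Exact duplicates are removed first, the order is shuffled by ``seed``,
    then each point is accepted iff it lies at least ``min_km`` from every
    point accepted so far.  The retained set is maximal under this rule: no
    discarded point can be added back without violating the distance floor.
    """
    if not min_km > 0:
        raise ValueError("min_km must be positive")
    occ = occ.dedupe()
    n = len(occ)
    if n <= 1:
        return occ
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    lons, lats = occ.lons, occ.lats
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lons[i], lats[i], lons[kept], lats[kept])
        if np.all(d >= min_km):
            kept.append(i)
    kept.sort()
    return OccurrenceSet([occ.records[i] for i in kept])


def thin_best_of(occ: OccurrenceSet, min_km: float, n_trials: int = 10,
                 seed: int = 0) -> OccurrenceSet:
    """Repeat seeded thinning and keep the largest retained set (ties: first)."""
    best = None
    for t in range(n_trials):
        cand = thin(occ, min_km, seed=seed + t)
        if best is None or len(cand) > len(best):
            best = cand
    return best


def split(occ: OccurrenceSet, train_fraction: float = 0.75,
          replicates: int = 10, seed: int = 0
          ) -> list[tuple[OccurrenceSet, OccurrenceSet]]:
    """Random train/test partitions (default 75/25 in 10 replicates)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        perm = rng.permutation(n)
        tr = sorted(perm[:n_train])
        te = sorted(perm[n_train:])
        out.append((OccurrenceSet([occ.records[i] for i in tr]),
                    OccurrenceSet([occ.records[i] for i in te])))
    return out
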