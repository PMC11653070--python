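"""Synthetic study scenes: smooth cross-correlated bioclim-like rasters,
presences drawn from a known suitability truth, and site compound tables
generated from a content equation.

The default scene emulates the structure of the real study system at desk
scale: 19 bioclim-style layers over a subtropical-China-like window with a
strongly autocorrelated temperature block (bio1-bio11) and precipitation
block (bio12-bio19), so collinearity screening has real work to do; a
Gaussian niche truth dominated by annual precipitation (bio12) with a
secondary annual-mean-temperature (bio1) axis; and presence-only sampling
proportional to suitability.  A scenario knob applies additive warming and
multiplicative precipitation change for similarity-surface and
centroid-migration experiments with a known expected direction of shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, RasterLayer, RasterStack
from .occurrences import OccurrenceRecord, OccurrenceSet
from .quality import LinearContentEquation

TEMPERATURE_VARS = tuple(f"bio{i}" for i in range(1, 12))
PRECIPITATION_VARS = tuple(f"bio{i}" for i in range(12, 20))

# loosely realistic subtropical means/SDs for the 19 bioclim summaries
_DEFAULT_MEANS = {
    "bio1": 15.0, "bio2": 9.0, "bio3": 28.0, "bio4": 800.0, "bio5": 30.0,
    "bio6": 0.5, "bio7": 29.0, "bio8": 24.0, "bio9": 6.0, "bio10": 25.5,
    "bio11": 4.5, "bio12": 1100.0, "bio13": 200.0, "bio14": 25.0,
    "bio15": 65.0, "bio16": 520.0, "bio17": 90.0, "bio18": 480.0,
    "bio19": 105.0,
}
_DEFAULT_SDS = {
    "bio1": 4.0, "bio2": 1.5, "bio3": 4.0, "bio4": 120.0, "bio5": 3.5,
    "bio6": 4.5, "bio7": 3.0, "bio8": 4.0, "bio9": 5.0, "bio10": 3.5,
    "bio11": 4.5, "bio12": 280.0, "bio13": 55.0, "bio14": 12.0,
    "bio15": 15.0, "bio16": 140.0, "bio17": 45.0, "bio18": 130.0,
    "bio19": 50.0,
}


@dataclass
class TruthTerm:
    """One Gaussian niche axis: optimum and breadth in raw variable units."""
    var: str
    optimum: float
    breadth: float
    weight: float = 1.0


@dataclass
class SceneConfig:
    spec: GridSpec = field(default_factory=lambda: GridSpec(
        n_rows=80, n_cols=80, x_min=100.0, y_min=22.0, cell_size=0.2))
    var_names: tuple[str, ...] = TEMPERATURE_VARS + PRECIPITATION_VARS
    means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    #: lag-1 correlation base within each variable block (AR(1) structure,
    #: r(i, j) = base^|i-j| — positive semi-definite by construction)
    temp_block_base: float = 0.93
    precip_block_base: float = 0.90
    smoothness_cells: float = 6.0
    #: a habitat specialist: annual precipitation about 1.2 SD above the
    #: landscape mean with a narrow tolerance, plus a secondary thermal axis —
    #: the restricted-range regime in which presence-background models of
    #: medicinal herbs typically operate (landscape suitability ceiling
    #: comparable to a discrimination AUC in the mid-0.9s)
    truth: tuple[TruthTerm, ...] = (
        TruthTerm("bio12", optimum=1450.0, breadth=60.0, weight=1.0),
        TruthTerm("bio1", optimum=16.5, breadth=1.3, weight=0.6),
    )
    n_presences: int = 200
    noise_sd_fraction: float = 0.10   # content noise as a fraction of response SD
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        names = list(self.var_names)
        k = len(names)
        corr = np.eye(k)
        for block, base in ((TEMPERATURE_VARS, self.temp_block_base),
                            (PRECIPITATION_VARS, self.precip_block_base)):
            idx = [names.index(v) for v in block if v in names]
            for a, i in enumerate(idx):
                for b, j in enumerate(idx):
                    corr[i, j] = base ** abs(a - b)
        return corr

    def to_yaml(self) -> str:
        d = {
            "spec": {"n_rows": self.spec.n_rows, "n_cols": self.spec.n_cols,
                     "x_min": self.spec.x_min, "y_min": self.spec.y_min,
                     "cell_size": self.spec.cell_size,
                     "nodata": self.spec.nodata},
            "var_names": list(self.var_names),
            "means": self.means, "sds": self.sds,
            "temp_block_base": self.temp_block_base,
            "precip_block_base": self.precip_block_base,
            "smoothness_cells": self.smoothness_cells,
            "truth": [vars(t) for t in self.truth],
            "n_presences": self.n_presences,
            "noise_sd_fraction": self.noise_sd_fraction,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneConfig":
        d = yaml.safe_load(text)
        return cls(
            spec=GridSpec(**d["spec"]),
            var_names=tuple(d["var_names"]),
            means=d["means"], sds=d["sds"],
            temp_block_base=d["temp_block_base"],
            precip_block_base=d["precip_block_base"],
            smoothness_cells=d["smoothness_cells"],
            truth=tuple(TruthTerm(**t) for t in d["truth"]),
            n_presences=d["n_presences"],
            noise_sd_fraction=d["noise_sd_fraction"],
            seed=d["seed"],
        )


def default_scene(seed: int = 0, **overrides) -> SceneConfig:
    return SceneConfig(seed=seed, **overrides)


def synth_climate_stack(config: SceneConfig) -> RasterStack:
    """Cross-correlated Gaussian random fields with the configured means,
    SDs and block correlations; bit-reproducible given the seed."""
    spec = config.spec
    names = list(config.var_names)
    k = len(names)
    corr = config.correlation_matrix()
    # Cholesky requires PSD; AR-block structure guarantees it
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is not positive semi-definite") from e
    rng = np.random.default_rng(config.seed)
    shape = (spec.n_rows, spec.n_cols)
    base = np.empty((k,) + shape)
    for i in range(k):
        white = rng.standard_normal(shape)
        if config.smoothness_cells > 0:
            f = gaussian_filter(white, sigma=config.smoothness_cells,
                                mode="reflect")
        else:
            f = white
        sd = f.std()
        base[i] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    mixed = np.tensordot(L, base, axes=(1, 0))
    layers = []
    for i, n in enumerate(names):
        vals = config.means[n] + config.sds[n] * mixed[i]
        layers.append(RasterLayer(spec, n, vals))
    return RasterStack(layers)


def synth_truth_suitability(stack: RasterStack,
                            truth: tuple[TruthTerm, ...]) -> RasterLayer:
    """Product-Gaussian niche response, in [0,1], maximal at the optimum."""
    spec = stack.spec
    expo = np.zeros((spec.n_rows, spec.n_cols))
    for t in truth:
        z = (stack[t.var].values - t.optimum) / t.breadth
        expo += t.weight * z * z / 2.0
    s = np.exp(-expo)
    mask = stack.mask
    return RasterLayer(spec, "truth_suitability",
                       np.where(mask, s, spec.nodata))


def sample_presences(truth: RasterLayer, n: int, seed: int = 0,
                     jitter: bool = True, replace: bool = False
                     ) -> OccurrenceSet:
    """Presence cells drawn with probability proportional to suitability,
    without replacement by default; points jittered uniformly in the cell."""
    mask = truth.mask & (truth.values > 0)
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        raise ValueError("truth surface has no positive mass")
    if not replace and n > flat.size:
        raise ValueError(f"cannot draw {n} distinct cells from {flat.size} "
                         "positive-mass cells")
    w = truth.values.ravel()[flat]
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=replace, p=p)
    rows, cols = np.unravel_index(chosen, mask.shape)
    spec = truth.spec
    if jitter:
        u = rng.random((n, 2))
    else:
        u = np.full((n, 2), 0.5)
    lons = spec.x_min + (cols + u[:, 0]) * spec.cell_size
    lats = spec.y_max - (rows + u[:, 1]) * spec.cell_size
    return OccurrenceSet([OccurrenceRecord(float(lo), float(la), "synthetic")
                          for lo, la in zip(lons, lats)])


def synth_compound_table(stack: RasterStack, sites: OccurrenceSet,
                         eq: LinearContentEquation, noise_sd: float,
                         nd_threshold: float | None = None, seed: int = 0):
    """Site table: equation response at each site's cell plus Gaussian noise;
    values below ``nd_threshold`` flagged as not detected (NaN response)."""
    import pandas as pd

    X = stack.values_at(sites.lons, sites.lats)
    bad = np.isnan(X).any(axis=1)
    if bad.any():
        raise ValueError(f"{bad.sum()} sites fall on nodata cells")
    df = pd.DataFrame(X, columns=stack.names)
    rng = np.random.default_rng(seed)
    y = eq.predict(df) + rng.normal(0.0, noise_sd, size=len(df))
    nd = np.zeros(len(df), bool) if nd_threshold is None else y < nd_threshold
    out = df.copy()
    out.insert(0, "site", np.arange(1, len(df) + 1))
    out[eq.response] = np.where(nd, np.nan, y)
    out["nd"] = nd
    return out


def scenario_stack(stack: RasterStack, temp_delta: float = 0.0,
                   precip_factor: float = 1.0,
                   temp_vars=TEMPERATURE_VARS,
                   precip_vars=PRECIPITATION_VARS) -> RasterStack:
    """A future-climate variant: additive warming on temperature variables,
    multiplicative change on precipitation variables."""
    layers = []
    for l in stack.layers:
        v = l.values.copy()
        m = l.mask
        if l.name in temp_vars:
            v = np.where(m, v + temp_delta, v)
        elif l.name in precip_vars:
            v = np.where(m, v * precip_factor, v)
        layers.append(RasterLayer(l.spec, l.name, v))
    return RasterStack(layers)
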