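"""Multivariate environmental similarity surface (MESS) and the most
dissimilar variable (MoD).

For one variable with reference values spanning [min, max] and query value p,
let f be the percentage of reference values strictly below p.  Similarity is

    f = 0:        100 * (p - min) / (max - min)        (negative: below range)
    0 < f <= 50:  2 f
    50 < f < 100: 2 (100 - f)
    f = 100:      100 * (max - p) / (max - min)        (negative: above range)

The surface value at a cell is the minimum similarity over variables; a
negative value marks extrapolation beyond the reference range (a climate
anomaly).  MoD is the variable attaining that minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterLayer, RasterStack


@dataclass
class MESSResult:
    mess: RasterLayer
    mod: RasterLayer                  # variable index of the minimum
    var_names: list[str]
    similarity_layers: list[RasterLayer] | None = None

    def mod_legend(self) -> dict[int, str]:
        return dict(enumerate(self.var_names))


def _similarity(ref: np.ndarray, p: np.ndarray) -> np.ndarray:
    ref = np.asarray(ref, float)
    rmin, rmax = ref.min(), ref.max()
    if rmax == rmin:
        raise ValueError("degenerate reference variable (max == min)")
    p = np.asarray(p, float)
    f = 100.0 * (ref[None, :] < p[..., None]).mean(axis=-1) \
        if p.ndim else 100.0 * np.mean(ref < p)
    f = np.asarray(f, float)
    sim = np.where(
        f == 0, 100.0 * (p - rmin) / (rmax - rmin),
        np.where(f <= 50, 2.0 * f,
                 np.where(f < 100, 2.0 * (100.0 - f),
                          100.0 * (rmax - p) / (rmax - rmin))))
    return sim


def mess_point(reference, p: float) -> float:
    """Similarity of a single query value to a reference sample."""
    return float(_similarity(np.asarray(reference, float), np.asarray(p, float)))


def mess_surface(reference: np.ndarray, query: RasterStack,
                 var_names: list[str] | None = None,
                 keep_layers: bool = False) -> MESSResult:
    """MESS and MoD over a query stack.

    ``reference`` is an (n_points, n_vars) matrix of environmental values at
    the reference points, column order matching ``var_names`` (defaults to the
    query stack's layer order).  Every reference variable must exist in the
    query stack.
    """
    reference = np.atleast_2d(np.asarray(reference, float))
    if var_names is None:
        var_names = list(query.names)
    if reference.shape[1] != len(var_names):
        raise ValueError(f"reference has {reference.shape[1]} columns for "
                         f"{len(var_names)} variable names")
    missing = [v for v in var_names if v not in query]
    if missing:
        raise KeyError(f"query stack is missing reference variables: {missing}")
    sub = query.subset(var_names)
    mask = sub.mask
    spec = query.spec
    sims = np.full((len(var_names),) + mask.shape, np.nan)
    for k, v in enumerate(var_names):
        vals = sub[v].values[mask]
        sims[k][mask] = _similarity(reference[:, k], vals)
    sims_filled = np.where(mask, sims, np.inf)
    stackmin = np.min(sims_filled, axis=0)
    argmin = np.argmin(sims_filled, axis=0)
    mess_vals = np.where(mask, stackmin, spec.nodata)
    mod_vals = np.where(mask, argmin.astype(float), spec.nodata)
    layers = None
    if keep_layers:
        layers = [RasterLayer(spec, f"similarity_{v}",
                              np.where(mask, sims[k], spec.nodata))
                  for k, v in enumerate(var_names)]
    return MESSResult(RasterLayer(spec, "mess", mess_vals),
                      RasterLayer(spec, "mod", mod_vals),
                      list(var_names), layers)


def mess_summary(result: MESSResult, areas: RasterLayer
                 ) -> tuple[float, float]:
    """Area-weighted mean similarity and fraction of area with negative
    similarity (extrapolation)."""
    mess = result.mess
    if not mess.spec.same_geometry(areas.spec):
        raise ValueError("mess and area layers are on different grids")
    m = mess.mask
    w = areas.values[m]
    v = mess.values[m]
    total = w.sum()
    return float((v * w).sum() / total), float(w[v < 0].sum() / total)
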