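"""Regularized maximum-entropy presence-background distribution model.

The model is the Gibbs distribution over landscape cells

    P(x) = exp(lambda . f(x)) / Z,   Z = sum over background cells,

whose coefficients maximize the mean presence log-density minus an L1
penalty  sum_j beta_j |lambda_j|  with per-feature weights

    beta_j = rm * lambda_class(m) * sqrt(var_j / m),

where m is the presence count, var_j the feature variance over presence
sites, and lambda_class(m) the per-feature-class base regularization
interpolated on sample size (the published defaults of the reference
presence-background tool).  Fitting is cyclic coordinate descent with
soft-thresholding on the L1 term.

Feature classes: L linear, Q quadratic, P pairwise products, H hinge
(both orientations, quantile knots), T threshold indicators.  All features
are built on variables min-max scaled to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterLayer, RasterStack
from .metrics import auc
from .occurrences import OccurrenceSet

VALID_CLASSES = set("LQHPT")


# ---------------------------------------------------------------------------
# Feature expansion

@dataclass(frozen=True)
class Feature:
    fclass: str                  # one of L Q H R T  (R = reverse hinge)
    var: str
    var2: str | None = None      # second variable for products
    knot: float | None = None    # scaled-space knot for hinge/threshold

    @property
    def penalty_class(self) -> str:
        # reverse hinges share the hinge class; products their own
        return {"R": "H"}.get(self.fclass, self.fclass)

    def label(self) -> str:
        if self.fclass == "P":
            return f"P({self.var}*{self.var2})"
        if self.fclass in ("H", "R", "T"):
            return f"{self.fclass}({self.var}@{self.knot:.4g})"
        return f"{self.fclass}({self.var})"


@dataclass
class FeatureExpansion:
    var_names: list[str]
    vmin: np.ndarray
    vmax: np.ndarray
    features: list[Feature]

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Min-max scale raw variables to [0,1], clamping outside the
        training range (standard projection-time clamping)."""
        rng = self.vmax - self.vmin
        return np.clip((X - self.vmin) / rng, 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Raw variable matrix (n, n_vars) -> design matrix (n, n_features)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.var_names):
            raise ValueError(
                f"expected {len(self.var_names)} variables "
                f"({self.var_names}), got {X.shape[1]}")
        Z = self.scale(X)
        col = {n: i for i, n in enumerate(self.var_names)}
        out = np.empty((X.shape[0], len(self.features)))
        for k, f in enumerate(self.features):
            z = Z[:, col[f.var]]
            if f.fclass == "L":
                out[:, k] = z
            elif f.fclass == "Q":
                out[:, k] = z * z
            elif f.fclass == "P":
                out[:, k] = z * Z[:, col[f.var2]]
            elif f.fclass == "H":
                out[:, k] = np.maximum(0.0, (z - f.knot) / (1.0 - f.knot))
            elif f.fclass == "R":
                out[:, k] = np.maximum(0.0, (f.knot - z) / f.knot)
            elif f.fclass == "T":
                out[:, k] = (z > f.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature class {f.fclass}")
        return out

    def variables_of(self, f: Feature) -> list[str]:
        return [f.var, f.var2] if f.fclass == "P" else [f.var]


def _quantile_knots(z: np.ndarray, count: int) -> np.ndarray:
    """Equally spaced quantiles of the scaled background values, strictly
    inside (0, 1); duplicates collapse."""
    qs = np.linspace(0, 1, count + 2)[1:-1]
    k = np.quantile(z, qs)
    k = np.unique(np.clip(k, 1e-6, 1 - 1e-6))
    return k


def build_features(var_names: list[str], X_pres: np.ndarray, X_bg: np.ndarray,
                   fc: str, hinge_knots: int = 50, threshold_knots: int = 50
                   ) -> tuple[FeatureExpansion, np.ndarray, np.ndarray]:
    """Build the feature expansion and the presence/background design matrices.

    ``fc`` is a string over {L,Q,H,P,T}.  Scaling bounds come from the pooled
    presence + background values; constant variables are excluded with a
    warning.  Returns (expansion, F_presence, F_background).
    """
    fc = fc.upper()
    if not fc or not set(fc) <= VALID_CLASSES:
        raise ValueError(f"feature classes must be a non-empty subset of LQHPT, got {fc!r}")
    X_pres = np.atleast_2d(X_pres)
    X_bg = np.atleast_2d(X_bg)
    pooled = np.vstack([X_pres, X_bg])
    vmin, vmax = pooled.min(axis=0), pooled.max(axis=0)
    keep = vmax > vmin
    if not keep.all():
        dropped = [n for n, k in zip(var_names, keep) if not k]
        warnings.warn(f"constant variables excluded from expansion: {dropped}")
    names = [n for n, k in zip(var_names, keep) if k]
    if not names:
        raise ValueError("all variables are constant; nothing to fit")
    vmin, vmax = vmin[keep], vmax[keep]
    Zbg = np.clip((X_bg[:, keep] - vmin) / (vmax - vmin), 0, 1)

    feats: list[Feature] = []
    if "L" in fc:
        feats += [Feature("L", n) for n in names]
    if "Q" in fc:
        feats += [Feature("Q", n) for n in names]
    if "P" in fc:
        feats += [Feature("P", a, b) for i, a in enumerate(names)
                  for b in names[i + 1:]]
    if "H" in fc:
        for j, n in enumerate(names):
            for k in _quantile_knots(Zbg[:, j], hinge_knots):
                feats.append(Feature("H", n, knot=float(k)))
                feats.append(Feature("R", n, knot=float(k)))
    if "T" in fc:
        for j, n in enumerate(names):
            for k in _quantile_knots(Zbg[:, j], threshold_knots):
                feats.append(Feature("T", n, knot=float(k)))

    exp = FeatureExpansion(names, vmin, vmax, feats)
    return exp, exp.transform(X_pres[:, keep]), exp.transform(X_bg[:, keep])


# ---------------------------------------------------------------------------
# Regularization defaults

def class_base_beta(fclass: str, m: int) -> float:
    """Per-class base L1 weight, interpolated log-linearly in presence count."""
    lm = np.log(m)
    if fclass in ("L", "Q", "P"):
        return float(np.interp(lm, np.log([10, 30, 100]), [1.0, 0.2, 0.05]))
    if fclass == "H":
        return 0.5
    if fclass == "T":
        return float(np.interp(lm, np.log([10, 100]), [2.0, 1.0]))
    raise ValueError(f"unknown feature class {fclass!r}")


# ---------------------------------------------------------------------------
# Model

@dataclass
class MaxEntModel:
    expansion: FeatureExpansion
    coefficients: np.ndarray
    rm: float
    fc: str
    log_partition: float          # log Z over the training background
    entropy_H: float              # entropy of fitted raw over background
    n_background: int
    converged: bool = True
    background_seed: int | None = None
    trace: list[tuple[int, float]] = field(default_factory=list, repr=False)
    bg_var_means: np.ndarray | None = None   # raw-variable background means

    def linear_predictor(self, X_raw: np.ndarray) -> np.ndarray:
        return self.expansion.transform(X_raw) @ self.coefficients

    def raw(self, X_raw: np.ndarray) -> np.ndarray:
        return np.exp(self.linear_predictor(X_raw) - self.log_partition)

    def suitability(self, X_raw: np.ndarray, transform: str = "cloglog") -> np.ndarray:
        return apply_transform(self.raw(X_raw), self.entropy_H, transform)

    def n_nonzero(self, tol: float = 1e-8) -> int:
        return int(np.sum(np.abs(self.coefficients) > tol))

    def to_json(self) -> str:
        e = self.expansion
        return json.dumps({
            "var_names": e.var_names,
            "vmin": e.vmin.tolist(), "vmax": e.vmax.tolist(),
            "features": [{"fclass": f.fclass, "var": f.var, "var2": f.var2,
                          "knot": f.knot} for f in e.features],
            "coefficients": self.coefficients.tolist(),
            "rm": self.rm, "fc": self.fc,
            "log_partition": self.log_partition, "entropy_H": self.entropy_H,
            "n_background": self.n_background, "converged": self.converged,
            "background_seed": self.background_seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        exp = FeatureExpansion(
            d["var_names"], np.array(d["vmin"]), np.array(d["vmax"]),
            [Feature(f["fclass"], f["var"], f["var2"], f["knot"])
             for f in d["features"]])
        return cls(exp, np.array(d["coefficients"]), d["rm"], d["fc"],
                   d["log_partition"], d["entropy_H"], d["n_background"],
                   d["converged"], d["background_seed"])


def apply_transform(raw: np.ndarray, entropy_H: float, transform: str,
                    tau: float = 0.5) -> np.ndarray:
    if transform == "raw":
        return raw
    r = np.exp(entropy_H) * raw
    if transform == "cloglog":
        return 1.0 - np.exp(-r)
    if transform == "logistic":
        return tau * r / ((1 - tau) + tau * r)
    raise ValueError(f"unknown transform {transform!r}")


def fit_maxent(F_pres: np.ndarray, F_bg: np.ndarray, rm: float = 1.0,
               feature_classes: list[str] | None = None,
               expansion: FeatureExpansion | None = None, fc: str = "",
               max_iter: int = 500, tol: float = 1e-5,
               n_background: int | None = None,
               background_seed: int | None = None) -> MaxEntModel:
    """Fit the penalized maximum-entropy model by cyclic coordinate descent.

    ``F_pres``/``F_bg`` are feature design matrices; ``feature_classes`` gives
    the penalty class per column (taken from ``expansion`` when omitted).
    The returned model's raw output sums to exactly 1 over the training
    background (hard postcondition).
    """
    F_pres = np.atleast_2d(np.asarray(F_pres, float))
    F_bg = np.atleast_2d(np.asarray(F_bg, float))
    m, p = F_pres.shape
    n_bg = F_bg.shape[0]
    if m < 5:
        raise ValueError(f"need at least 5 presences, got {m}")
    if n_bg < m:
        raise ValueError("background must be at least as large as presences")
    if feature_classes is None:
        if expansion is None:
            raise ValueError("provide feature_classes or expansion")
        feature_classes = [f.penalty_class for f in expansion.features]
    if np.all(np.ptp(F_bg, axis=0) == 0) and np.all(np.ptp(F_pres, axis=0) == 0):
        raise ValueError("all features are constant")

    f_pres_mean = F_pres.mean(axis=0)
    var_pres = F_pres.var(axis=0)
    beta = np.array([
        rm * class_base_beta(c, m) * np.sqrt(max(var_pres[j], 1e-12) / m)
        for j, c in enumerate(feature_classes)])

    lam = np.zeros(p)
    # unnormalized background weights, kept stable via an offset
    log_u = np.zeros(n_bg)
    trace: list[tuple[int, float]] = []

    def logZ():
        mx = log_u.max()
        return mx + np.log(np.exp(log_u - mx).sum())

    lz = logZ()
    obj = lam @ f_pres_mean - lz  # penalty is 0 at lam=0
    converged = False
    for sweep in range(max_iter):
        obj_start = obj
        for j in range(p):
            w = np.exp(log_u - lz)          # normalized weights, sum 1
            fj = F_bg[:, j]
            ef = w @ fj
            ef2 = w @ (fj * fj)
            h = ef2 - ef * ef
            if h < 1e-12:
                continue
            g = f_pres_mean[j] - ef
            z = lam[j] + g / h
            new = np.sign(z) * max(abs(z) - beta[j] / h, 0.0)
            step = np.clip(new - lam[j], -4.0, 4.0)
            if step == 0.0:
                continue
            lam[j] += step
            log_u = log_u + step * fj
            lz = logZ()
            new_obj = lam @ f_pres_mean - lz - beta @ np.abs(lam)
            trace.append((j, new_obj - obj))
            obj = new_obj
        if abs(obj - obj_start) < tol * max(1.0, abs(obj_start)):
            converged = True
            break
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {max_iter} sweeps")

    w = np.exp(log_u - lz)
    wpos = w[w > 0]
    entropy = float(-(wpos * np.log(wpos)).sum())
    # raw = exp(eta - log_partition); eta here is F_bg @ lam = log_u
    log_partition = float(lz)
    model = MaxEntModel(
        expansion=expansion, coefficients=lam, rm=rm,
        fc=fc or "".join(sorted(set(feature_classes))),
        log_partition=log_partition, entropy_H=entropy,
        n_background=n_bg, converged=converged,
        background_seed=background_seed, trace=trace)
    total = float(np.exp(F_bg @ lam - log_partition).sum())
    assert abs(total - 1.0) < 1e-6, f"raw does not sum to 1 over background ({total})"
    return model


# ---------------------------------------------------------------------------
# Pipeline conveniences

def sample_background(stack: RasterStack, n: int = 10_000, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Random background cells: returns (flat cell indices, raw matrix)."""
    mask = stack.mask
    flat = np.flatnonzero(mask.ravel())
    rng = np.random.default_rng(seed)
    if len(flat) > n:
        flat = rng.choice(flat, size=n, replace=False)
        flat.sort()
    rows, cols = np.unravel_index(flat, mask.shape)
    X = np.column_stack([l.values[rows, cols] for l in stack.layers])
    return flat, X


def presence_matrix(stack: RasterStack, presences: OccurrenceSet,
                    collapse_cells: bool = True) -> np.ndarray:
    """Environmental values at presence points; duplicates per cell collapsed
    by default; points on nodata cells dropped with a warning."""
    row, col = stack.spec.cell_of(presences.lons, presences.lats)
    ok = row >= 0
    valid = stack.mask
    ok &= np.where(ok, valid[row.clip(0), col.clip(0)], False)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} presence points on nodata/off-grid cells dropped")
    row, col = row[ok], col[ok]
    if collapse_cells:
        _, first = np.unique(row * valid.shape[1] + col, return_index=True)
        row, col = row[np.sort(first)], col[np.sort(first)]
    return np.column_stack([l.values[row, col] for l in stack.layers])


def fit_sdm(stack: RasterStack, presences: OccurrenceSet, fc: str = "LQH",
            rm: float = 1.0, background_size: int = 10_000, seed: int = 0,
            hinge_knots: int = 50, threshold_knots: int = 50,
            add_presences_to_background: bool = True,
            collapse_cells: bool = True, max_iter: int = 500,
            tol: float = 1e-5) -> MaxEntModel:
    """Sample background, expand features and fit in one call."""
    X_pres = presence_matrix(stack, presences, collapse_cells)
    _, X_bg = sample_background(stack, background_size, seed)
    if add_presences_to_background:
        X_bg = np.vstack([X_bg, X_pres])
    exp, F_pres, F_bg = build_features(stack.names, X_pres, X_bg, fc,
                                       hinge_knots, threshold_knots)
    model = fit_maxent(F_pres, F_bg, rm=rm, expansion=exp, fc=fc,
                       max_iter=max_iter, tol=tol, background_seed=seed)
    model.bg_var_means = X_bg.mean(axis=0)
    return model


def predict(model: MaxEntModel, stack: RasterStack,
            transform: str = "cloglog") -> RasterLayer:
    """Project the model onto a stack, returning a suitability layer."""
    missing = [v for v in model.expansion.var_names if v not in stack]
    if missing:
        raise KeyError(f"stack is missing model variables: {missing}")
    sub = stack.subset(model.expansion.var_names)
    mask = sub.mask
    X = sub.table(mask)
    s = model.suitability(X, transform)
    out = np.full(mask.shape, stack.spec.nodata)
    out[mask] = s
    return RasterLayer(stack.spec, f"suitability_{transform}", out)


# ---------------------------------------------------------------------------
# Diagnostics

def percent_contribution(model: MaxEntModel) -> dict[str, float]:
    """Per-variable share of the accumulated training-objective gain.

    Coordinate-update gains are attributed to the updated feature's source
    variable (product features split evenly between their two variables),
    negative accumulations floored at zero, then normalized to sum 100.
    A gainless (null) model returns all zeros.
    """
    if model.trace is None or model.expansion is None:
        raise ValueError("fit trace unavailable; refit with trace recording")
    gains = {v: 0.0 for v in model.expansion.var_names}
    feats = model.expansion.features
    for j, g in model.trace:
        vs = model.expansion.variables_of(feats[j])
        for v in vs:
            gains[v] += g / len(vs)
    gains = {v: max(0.0, g) for v, g in gains.items()}
    total = sum(gains.values())
    if total <= 0:
        return {v: 0.0 for v in gains}
    return {v: 100.0 * g / total for v, g in gains.items()}


def permutation_importance(model: MaxEntModel, X_pres: np.ndarray,
                           X_bg: np.ndarray, seed: int = 0) -> dict[str, float]:
    """Normalized training-AUC drop when each variable is permuted across the
    pooled presence + background rows."""
    rng = np.random.default_rng(seed)
    base = auc(model.linear_predictor(X_pres), model.linear_predictor(X_bg))
    m = X_pres.shape[0]
    drops = {}
    for k, v in enumerate(model.expansion.var_names):
        pooled = np.concatenate([X_pres[:, k], X_bg[:, k]])
        perm = rng.permutation(pooled)
        Xp, Xb = X_pres.copy(), X_bg.copy()
        Xp[:, k], Xb[:, k] = perm[:m], perm[m:]
        a = auc(model.linear_predictor(Xp), model.linear_predictor(Xb))
        drops[v] = max(0.0, base - a)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def training_gain(model: MaxEntModel, F_pres: np.ndarray) -> float:
    """Regularized training gain: improvement of the mean presence
    log-density over the uniform background model."""
    ll = float((F_pres @ model.coefficients).mean() - model.log_partition)
    return ll + np.log(model.n_background)


def jackknife_gain(stack: RasterStack, presences: OccurrenceSet,
                   fc: str = "LQH", rm: float = 1.0,
                   background_size: int = 10_000, seed: int = 0,
                   **fit_kw) -> dict[str, tuple[float, float, float]]:
    """Training gain with each variable alone, withheld, and the full model.

    Returns {variable: (gain_only, gain_without, gain_full)}.
    """
    if len(stack) < 2:
        raise ValueError("jackknife needs at least two variables")

    def gain_for(names: list[str]) -> float:
        sub = stack.subset(names)
        model = fit_sdm(sub, presences, fc=fc, rm=rm,
                        background_size=background_size, seed=seed, **fit_kw)
        X_pres = presence_matrix(sub, presences)
        return training_gain(model, model.expansion.transform(X_pres))

    full = gain_for(stack.names)
    out = {}
    for v in stack.names:
        only = gain_for([v])
        without = gain_for([n for n in stack.names if n != v])
        out[v] = (only, without, full)
    return out


def response_curve(model: MaxEntModel, variable: str, grid: int = 100
                   ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Marginal response: sweep one variable over its training range with the
    others held at background means.  Returns (values, cloglog output,
    intervals where output > 0.5)."""
    exp = model.expansion
    if variable not in exp.var_names:
        raise KeyError(f"variable {variable!r} not in the model expansion")
    if model.bg_var_means is None:
        raise ValueError("background variable means unavailable on this model")
    k = exp.var_names.index(variable)
    xs = np.linspace(exp.vmin[k], exp.vmax[k], grid)
    X = np.tile(model.bg_var_means, (grid, 1))
    X[:, k] = xs
    ys = model.suitability(X, "cloglog")
    intervals = []
    above = ys > 0.5
    i = 0
    while i < grid:
        if above[i]:
            j = i
            while j + 1 < grid and above[j + 1]:
                j += 1
            intervals.append((float(xs[i]), float(xs[j])))
            i = j + 1
        else:
            i += 1
    return xs, ys, intervals
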