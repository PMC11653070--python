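"""Assay mathematics and bioclim regression of bioactive-compound content.

Covers the phenol-sulfuric-acid polysaccharide assay (glucose calibration
line, content formula ``content% = c*d*f/w * 100`` with conversion factor
f = 2.38), stepwise multiple linear regression of site-level compound
content on bioclim variables, the published regression equations for
polysaccharide and heterophyllin B content of Pseudostellariae Radix, and
their cellwise application to raster stacks to map predicted quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import RasterLayer, RasterStack
from .habitat import HabitatClassMap, jenks_breaks

#: polysaccharide-to-glucose conversion factor of the assay
CONVERSION_FACTOR = 2.38

#: glucose reference-solution protocol: 15.07 mg dried glucose in 25 mL
GLUCOSE_MASS_MG = 15.07
GLUCOSE_VOLUME_ML = 25.0
#: aliquots (mL) taken into the calibration series, and the final volume
#: implied by the printed standard concentrations
CALIBRATION_ALIQUOTS_ML = (0.5, 0.8, 1.0, 1.3, 1.5, 1.8)
CALIBRATION_FINAL_VOLUME_ML = 100.0


# ---------------------------------------------------------------------------
# Assay math

@dataclass(frozen=True)
class CalibrationCurve:
    slope: float        # absorbance per ug/mL
    intercept: float    # absorbance
    r: float            # Pearson correlation of the fit

    def concentration(self, absorbance: float) -> float:
        """Invert the line; negative concentrations clamp to 0 with a warning."""
        c = (absorbance - self.intercept) / self.slope
        if np.any(np.asarray(c) < 0):
            warnings.warn("absorbance below the calibration intercept; "
                          "concentration clamped to 0")
        return float(np.maximum(c, 0.0)) if np.isscalar(c) else np.maximum(c, 0.0)


#: the published glucose calibration line (489 nm)
REFERENCE_CALIBRATION = CalibrationCurve(slope=0.0548, intercept=0.0042, r=0.9996)


def glucose_stock(mass_mg: float, volume_ml: float) -> float:
    """Stock concentration in ug/mL from a dried mass in a volumetric flask."""
    if mass_mg <= 0 or volume_ml <= 0:
        raise ValueError("mass and volume must be positive")
    return 1000.0 * mass_mg / volume_ml


def dilute(stock_ug_ml: float, aliquot_ml: float, final_ml: float) -> float:
    """Concentration after transferring an aliquot into a final volume."""
    if stock_ug_ml < 0 or aliquot_ml <= 0 or final_ml <= 0:
        raise ValueError("volumes must be positive")
    return stock_ug_ml * aliquot_ml / final_ml


def calibration_series(mass_mg: float = GLUCOSE_MASS_MG,
                       volume_ml: float = GLUCOSE_VOLUME_ML,
                       aliquots_ml=CALIBRATION_ALIQUOTS_ML,
                       final_ml: float = CALIBRATION_FINAL_VOLUME_ML
                       ) -> np.ndarray:
    """Concentrations (ug/mL) of the calibration standards."""
    stock = glucose_stock(mass_mg, volume_ml)
    return np.array([dilute(stock, a, final_ml) for a in aliquots_ml])


def fit_calibration(points) -> CalibrationCurve:
    """OLS of absorbance on concentration for (concentration, absorbance) pairs."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, absorbance) pairs")
    c, a = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 2:
        raise ValueError("all concentrations identical; line undefined")
    slope, intercept = np.polyfit(c, a, 1)
    if a.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(c, a)[0, 1])
    return CalibrationCurve(float(slope), float(intercept), r)


def polysaccharide_content(absorbance: float, curve: CalibrationCurve,
                           dilution_factor: float,
                           sample_mass_g: float,
                           conversion_factor: float = CONVERSION_FACTOR
                           ) -> float:
    """Percent polysaccharide: (c * d * f / w) * 100.

    ``c`` (ug/mL) comes from inverting the calibration line; ``d`` carries
    all volume/unit bookkeeping of the extraction protocol (configured by the
    caller), ``f`` the glucose-to-polysaccharide conversion, ``w`` the sample
    mass in g.
    """
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    c = curve.concentration(absorbance)
    return c * dilution_factor * conversion_factor / sample_mass_g * 100.0


# ---------------------------------------------------------------------------
# Content equations

@dataclass(frozen=True)
class LinearContentEquation:
    """Linear map from named bioclim variables to compound content."""

    response: str
    intercept: float
    terms: tuple[tuple[str, float], ...]

    @property
    def variables(self) -> list[str]:
        return [v for v, _ in self.terms]

    def predict(self, values: dict[str, float] | pd.DataFrame) -> np.ndarray:
        if isinstance(values, dict):
            values = pd.DataFrame([values])
        y = np.full(len(values), self.intercept, float)
        for v, coef in self.terms:
            y = y + coef * values[v].to_numpy(float)
        return y


#: published stepwise-regression equation for polysaccharide content (%)
#: on bioclim predictors (R^2 = 0.466)
POLYSACCHARIDE_EQUATION = LinearContentEquation(
    response="polysaccharide",
    intercept=-79.109,
    terms=(("bio6", 2.461), ("bio1", -3.435), ("bio2", -8.893),
           ("bio3", 4.307), ("bio4", 0.126), ("bio12", -0.016),
           ("bio14", 0.422), ("bio16", 0.04)),
)

#: published stepwise-regression equation for heterophyllin B content (%)
#: on bioclim predictors (R^2 = 0.467)
HETEROPHYLLIN_B_EQUATION = LinearContentEquation(
    response="heterophyllin_b",
    intercept=0.013,
    terms=(("bio6", 0.001), ("bio2", -0.009), ("bio3", 0.002),
           ("bio4", 0.0007578), ("bio12", -0.0003139), ("bio16", 0.0001476)),
)


# ---------------------------------------------------------------------------
# Site table fixture

def load_content_table() -> pd.DataFrame:
    """The packaged 44-site compound-content table.

    Columns: site, place, poly_mean, poly_sd, hb_mean, hb_sd, hb_nd.
    ``hb_nd`` marks heterophyllin B below the quantification limit; such rows
    carry NaN means.  Contents are percent mass fraction (mean +/- SD of
    three assay replicates per site).
    """
    with resources.files("herbniche.data").joinpath("content_sites.csv").open() as fh:
        df = pd.read_csv(fh)
    df["hb_nd"] = df["hb_nd"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Stepwise regression

@dataclass
class RegressionModel:
    equation: LinearContentEquation
    r_squared: float
    p_value: float
    alpha_enter: float
    alpha_remove: float
    step_log: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return self.equation.intercept

    @property
    def terms(self) -> tuple[tuple[str, float], ...]:
        return self.equation.terms


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(table: pd.DataFrame, response: str,
                        predictors: list[str] | None = None,
                        alpha_enter: float = 0.05,
                        alpha_remove: float = 0.10) -> RegressionModel:
    """Forward-entry / backward-removal stepwise OLS.

    At each step the candidate with the smallest partial-F p-value below
    ``alpha_enter`` enters; any included term whose p-value exceeds
    ``alpha_remove`` is then removed (largest first).  Iterates to a fixpoint.
    Rows with a missing response are excluded (e.g. not-detected sites).
    Near-collinear candidates that make the design singular are skipped.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    data = table[[response] + list(predictors)].dropna(subset=[response])
    y = data[response].to_numpy(float)
    n = len(data)
    if n <= 3:
        raise ValueError(f"too few complete observations ({n})")
    included: list[str] = []
    log: list[str] = []
    seen_states = set()
    while True:
        state = tuple(sorted(included))
        if state in seen_states:
            log.append("cycle detected; stopping")
            break
        seen_states.add(state)
        changed = False
        # forward step
        best_p, best_var = np.inf, None
        for cand in predictors:
            if cand in included:
                continue
            if n <= len(included) + 3:
                break  # not enough df for another term
            X = data[included + [cand]]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) \
                    < len(included) + 2:
                log.append(f"skip {cand}: collinear with current model")
                continue
            fit = _ols(y, X)
            p = float(fit.pvalues[cand])
            if p < best_p:
                best_p, best_var = p, cand
        if best_var is not None and best_p < alpha_enter:
            included.append(best_var)
            log.append(f"enter {best_var} (p={best_p:.4g})")
            changed = True
        # backward step
        while included:
            fit = _ols(y, data[included])
            pvals = fit.pvalues[included]
            worst = pvals.idxmax()
            if float(pvals[worst]) > alpha_remove:
                included.remove(worst)
                log.append(f"remove {worst} (p={float(pvals[worst]):.4g})")
                changed = True
            else:
                break
        if not changed:
            break

    if included:
        fit = _ols(y, data[included])
        eq = LinearContentEquation(
            response=response, intercept=float(fit.params["const"]),
            terms=tuple((v, float(fit.params[v])) for v in included))
        r2, pval = float(fit.rsquared), float(fit.f_pvalue)
    else:
        eq = LinearContentEquation(response=response,
                                   intercept=float(np.mean(y)), terms=())
        r2, pval = 0.0, 1.0
    return RegressionModel(eq, r2, pval, alpha_enter, alpha_remove, log)


# ---------------------------------------------------------------------------
# Spatial application

def apply_content_equation(eq: LinearContentEquation | RegressionModel,
                           stack: RasterStack) -> RasterLayer:
    """Evaluate a content equation cellwise over a raster stack."""
    if isinstance(eq, RegressionModel):
        eq = eq.equation
    missing = [v for v in eq.variables if v not in stack]
    if missing:
        raise KeyError(f"stack is missing equation variables: {missing}")
    mask = stack.mask
    out = np.full(mask.shape, float(eq.intercept))
    for v, coef in eq.terms:
        out = out + coef * stack[v].values
    out = np.where(mask, out, stack.spec.nodata)
    return RasterLayer(stack.spec, f"predicted_{eq.response}", out)


def classify_quality(content: RasterLayer, mode: str = "jenks3",
                     edges: tuple[float, float] | None = None,
                     mask: HabitatClassMap | None = None,
                     max_sample: int = 5000, seed: int = 0) -> RasterLayer:
    """Three-class (low / intermediate / high) map of predicted content.

    mode='jenks3' places the two cut points by natural breaks over the valid
    (optionally habitat-masked) cells, subsampling above ``max_sample`` for
    tractability; mode='fixed_edges' uses user-supplied cut points, e.g. the
    current-period breaks frozen for reuse across future scenarios.
    """
    m = content.mask
    if mask is not None:
        keep = np.zeros(m.shape, bool)
        for c in ("secondary", "suitable", "optimal"):
            keep |= mask.class_mask(c)
        m = m & keep
    vals = content.values[m]
    if mode == "jenks3":
        if len(np.unique(vals)) < 3:
            raise ValueError("fewer than 3 distinct content values; "
                             "classes degenerate")
        sample = vals
        if vals.size > max_sample:
            rng = np.random.default_rng(seed)
            sample = rng.choice(vals, size=max_sample, replace=False)
            if len(np.unique(sample)) < 3:
                sample = vals
        e1, e2 = jenks_breaks(sample, 3)
    elif mode == "fixed_edges":
        if edges is None or not edges[0] < edges[1]:
            raise ValueError("fixed_edges mode needs strictly increasing edges")
        e1, e2 = edges
    else:
        raise ValueError(f"unknown mode {mode!r}")
    codes = np.digitize(content.values, [e1, e2], right=True).astype(float)
    codes = np.where(m, codes, content.spec.nodata)
    layer = RasterLayer(content.spec, f"{content.name}_class", codes)
    layer.quality_edges = (float(e1), float(e2))  # type: ignore[attr-defined]
    return layer
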