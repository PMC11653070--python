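"""Tuning of the regularization multiplier and feature-class combination.

The default grid crosses eight multipliers (0.5 to 4 in steps of 0.5) with
nine feature-class sets (L, LQ, H, LQH, LQHP, LQHPT, QHP, QHPT, HPT), 72
candidate configurations in all.  Each is scored by AICc (presence
log-likelihood of the raw density normalized over the whole projection grid)
plus replicate train/test AUC and the 10% training omission rate; the cell
with delta-AICc = 0 is selected, ties broken by lower OR10, then lower
train-test AUC difference, then fewer nonzero coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterLayer, RasterStack
from .maxent import MaxEntModel, fit_sdm, presence_matrix, sample_background
from .metrics import aicc, auc, or10, tss_max
from .occurrences import OccurrenceSet, split

DEFAULT_RM_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_FC_SETS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT", "QHP", "QHPT", "HPT")


def default_grid(rm_values=DEFAULT_RM_VALUES, fc_sets=DEFAULT_FC_SETS
                 ) -> list[tuple[float, str]]:
    """Enumerate the (rm, fc) tuning grid (72 cells by default)."""
    return [(rm, fc) for rm in rm_values for fc in fc_sets]


@dataclass
class TuningRecord:
    rm: float
    fc: str
    k_nonzero: int = 0
    lnL: float = np.nan
    aicc: float = np.nan
    delta_aicc: float = np.nan
    auc_train: float = np.nan
    auc_test: float = np.nan
    auc_diff: float = np.nan
    or10: float = np.nan
    error: str | None = None

    @property
    def aicc_defined(self) -> bool:
        return np.isfinite(self.aicc)


def grid_log_likelihood(model: MaxEntModel, stack: RasterStack,
                        presences: OccurrenceSet) -> float:
    """Presence log-likelihood under raw normalized over all valid cells of
    the projection grid (the usual convention for SDM AICc)."""
    sub = stack.subset(model.expansion.var_names)
    X_all = sub.table()
    eta_all = model.linear_predictor(X_all)
    mx = eta_all.max()
    logZ = mx + np.log(np.exp(eta_all - mx).sum())
    X_pres = presence_matrix(sub, presences)
    eta_pres = model.linear_predictor(X_pres)
    return float((eta_pres - logZ).sum())


def tune_grid(stack: RasterStack, presences: OccurrenceSet,
              rm_values=DEFAULT_RM_VALUES, fc_sets=DEFAULT_FC_SETS,
              train_fraction: float = 0.75, replicates: int = 10,
              background_size: int = 10_000, seed: int = 0,
              **fit_kw) -> tuple[list[TuningRecord], TuningRecord]:
    """Fit and score every grid cell; returns (records, selected record).

    A failed fit is recorded with its error and the grid continues.
    """
    records: list[TuningRecord] = []
    splits = split(presences, train_fraction, replicates, seed=seed)
    _, X_bg = sample_background(stack, background_size, seed)
    for rm, fc in default_grid(rm_values, fc_sets):
        rec = TuningRecord(rm=rm, fc=fc)
        try:
            model = fit_sdm(stack, presences, fc=fc, rm=rm,
                            background_size=background_size, seed=seed,
                            **fit_kw)
            rec.k_nonzero = model.n_nonzero()
            rec.lnL = grid_log_likelihood(model, stack, presences)
            n = len(presences)
            if n > rec.k_nonzero + 1:
                rec.aicc = aicc(rec.lnL, rec.k_nonzero, n)
            bg_scores_cache = None
            a_tr, a_te, o10 = [], [], []
            for tr, te in splits:
                mrep = fit_sdm(stack, tr, fc=fc, rm=rm,
                               background_size=background_size, seed=seed,
                               **fit_kw)
                s_tr = mrep.suitability(presence_matrix(stack, tr), "cloglog")
                s_te = mrep.suitability(presence_matrix(stack, te), "cloglog")
                s_bg = mrep.suitability(X_bg, "cloglog")
                a_tr.append(auc(s_tr, s_bg))
                a_te.append(auc(s_te, s_bg))
                if len(s_tr) >= 10:
                    o10.append(or10(s_tr, s_te))
            rec.auc_train = float(np.mean(a_tr))
            rec.auc_test = float(np.mean(a_te))
            rec.auc_diff = rec.auc_train - rec.auc_test
            rec.or10 = float(np.mean(o10)) if o10 else np.nan
        except Exception as e:  # noqa: BLE001 - grid must survive cell failures
            rec.error = f"{type(e).__name__}: {e}"
        records.append(rec)

    defined = [r for r in records if r.aicc_defined]
    if not defined:
        raise RuntimeError("no grid cell produced a defined AICc")
    best_aicc = min(r.aicc for r in defined)
    for r in defined:
        r.delta_aicc = r.aicc - best_aicc
    selected = min(defined, key=lambda r: (
        r.delta_aicc,
        r.or10 if np.isfinite(r.or10) else np.inf,
        r.auc_diff if np.isfinite(r.auc_diff) else np.inf,
        r.k_nonzero))
    return records, selected


def tuning_frame(records: list[TuningRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def evaluate_replicates(stack: RasterStack, presences: OccurrenceSet,
                        fc: str = "LQH", rm: float = 1.0,
                        train_fraction: float = 0.75, replicates: int = 10,
                        background_size: int = 10_000, seed: int = 0,
                        **fit_kw) -> pd.DataFrame:
    """Replicate train/test evaluation of one configuration (AUC, TSS, OR10);
    one row per replicate, mean +/- SD obtainable from the frame."""
    _, X_bg = sample_background(stack, background_size, seed)
    rows = []
    for i, (tr, te) in enumerate(split(presences, train_fraction, replicates,
                                       seed=seed)):
        model = fit_sdm(stack, tr, fc=fc, rm=rm,
                        background_size=background_size, seed=seed, **fit_kw)
        s_tr = model.suitability(presence_matrix(stack, tr), "cloglog")
        s_te = model.suitability(presence_matrix(stack, te), "cloglog")
        s_bg = model.suitability(X_bg, "cloglog")
        tss, thr = tss_max(s_te, s_bg)
        rows.append({
            "replicate": i,
            "auc_train": auc(s_tr, s_bg),
            "auc_test": auc(s_te, s_bg),
            "tss": tss, "tss_threshold": thr,
            "or10": or10(s_tr, s_te) if len(s_tr) >= 10 else np.nan,
        })
    return pd.DataFrame(rows)


def envelope_baseline(stack: RasterStack, presences: OccurrenceSet,
                      percentile: float = 0.05) -> RasterLayer:
    """Surface-range-envelope baseline: each cell scores the fraction of
    variables whose value lies within the presence percentile envelope
    [p, 1-p].  A simple reference model for harness comparisons."""
    if len(presences) < 2:
        raise ValueError("envelope needs at least 2 presences")
    X_pres = presence_matrix(stack, presences, collapse_cells=False)
    lo = np.percentile(X_pres, 100 * percentile, axis=0)
    hi = np.percentile(X_pres, 100 * (1 - percentile), axis=0)
    mask = stack.mask
    X = stack.table(mask)
    inside = ((X >= lo) & (X <= hi)).mean(axis=1)
    out = np.full(mask.shape, stack.spec.nodata)
    out[mask] = inside
    return RasterLayer(stack.spec, "envelope_score", out)
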