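"""Presence-background evaluation metrics: AUC, maximized TSS, the 10%
training omission rate, and small-sample AICc."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EvalMetrics:
    auc_train: float
    auc_test: float
    tss: float
    tss_threshold: float
    or10: float


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def tss_max(presence_scores, background_scores) -> tuple[float, float]:
    """Maximum of sensitivity + specificity - 1 over all observed thresholds.

    A cell scoring >= threshold is predicted present.
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    best, best_t = -np.inf, np.nan
    for t in np.unique(np.concatenate([p, b])):
        sens = np.mean(p >= t)
        spec = np.mean(b < t)
        tss = sens + spec - 1
        if tss > best:
            best, best_t = tss, t
    return float(best), float(best_t)


def or10(train_scores, test_scores) -> float:
    """Test omission at the threshold excluding the lowest 10% of training
    presences (strictly-below counting)."""
    tr = np.asarray(train_scores, float)
    te = np.asarray(test_scores, float)
    if tr.size < 10:
        raise ValueError(f"need >= 10 training scores for OR10, got {tr.size}")
    thr = np.percentile(tr, 10)
    return float(np.mean(te < thr))


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: 2k - 2 lnL + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
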