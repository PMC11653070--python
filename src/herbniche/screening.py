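"""Pairwise Pearson correlation screening of environmental variables.

Collinear predictors degrade presence-background models; the standard remedy
is to drop one variable of every pair with |r| at or above a threshold
(0.8 by default), keeping the variable judged more ecologically meaningful.
That judgement is supplied as an explicit priority ordering so the screen is
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterStack
from .occurrences import OccurrenceSet


@dataclass
class CorrelationReport:
    names: list[str]
    matrix: np.ndarray           # symmetric, unit diagonal
    n_obs: int
    constant: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)

    def r(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])


def pearson_matrix(stack: RasterStack, mode: str = "cells",
                   points: OccurrenceSet | None = None) -> CorrelationReport:
    """Pearson r between all layer pairs.

    mode='cells' correlates over all jointly valid raster cells;
    mode='at_points' over the values extracted at occurrence points.
    Constant variables have undefined r; they are flagged and their pairwise
    entries set to 0 so downstream screening never drops them for collinearity.
    """
    if len(stack) < 2:
        raise ValueError("need at least two variables")
    if mode == "cells":
        X = stack.table()
    elif mode == "at_points":
        if points is None or len(points) == 0:
            raise ValueError("mode='at_points' requires occurrence points")
        X = stack.values_at(points.lons, points.lats)
        X = X[~np.isnan(X).any(axis=1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if X.shape[0] < 3:
        raise ValueError(f"only {X.shape[0]} joint observations; need >= 3")
    sd = X.std(axis=0)
    constant = [n for n, s in zip(stack.names, sd) if s == 0]
    if constant:
        warnings.warn(f"constant variables (r undefined, treated as 0): {constant}")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(X, rowvar=False)
    m = np.where(np.isnan(m), 0.0, m)
    np.fill_diagonal(m, 1.0)
    return CorrelationReport(list(stack.names), m, X.shape[0], constant=constant)


def collinearity_filter(report: CorrelationReport, threshold: float = 0.8,
                        priority: list[str] | None = None) -> list[str]:
    """Greedy priority-ordered screen: keep a variable, drop all its
    conflictors with |r| >= threshold, continue down the priority list.

    The result never contains a pair at or above the threshold, and within
    any conflicting pair the higher-priority variable survives.
    """
    names = report.names
    priority = list(priority) if priority is not None else list(names)
    missing = set(names) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover variables: {sorted(missing)}")
    idx = {n: i for i, n in enumerate(names)}
    retained: list[str] = []
    dropped: set[str] = set()
    report.dropped = []
    for name in priority:
        if name not in idx or name in dropped:
            continue
        retained.append(name)
        for other in priority:
            if other == name or other in dropped or other not in idx:
                continue
            if other in retained:
                continue
            r = report.matrix[idx[name], idx[other]]
            if abs(r) >= threshold:
                dropped.add(other)
                report.dropped.append((other, name, float(r)))
    # post-hoc assertion: no violating pair survives
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            assert abs(report.matrix[idx[a], idx[b]]) < threshold, \
                f"screen failed: |r({a},{b})| >= {threshold}"
    return retained


def screening_report_csv(report: CorrelationReport, retained: list[str], path) -> None:
    report.to_frame().to_csv(path)
    decisions = pd.DataFrame(report.dropped,
                             columns=["dropped", "retained_conflictor", "r"])
    decisions["kept_set"] = ", ".join(retained)
    decisions.to_csv(str(path).replace(".csv", "_drops.csv"), index=False)
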