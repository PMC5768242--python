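"""Rank correlation and t statistics, computed by formula.

The statistics the analysis rests on are deliberately implemented from
their definitions -- midrank Spearman correlation and Student t from
mean/SEM -- so each can be audited against an independent oracle; only the
Student-t distribution function (for p-values) comes from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "midranks",
    "spearman_rho",
    "one_sample_t",
    "paired_t",
]


@dataclass(frozen=True)
class CorrelationResult:
    hemisphere_id: str
    rho: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: int
    p: float
    mean: float
    sem: float


def midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values receiving the average of their ranks."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        # positions i..j share the same value: average rank
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of midranks.

    Returns NaN when either variable has zero rank variance (all values
    tied), where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0:
        return float("nan")
    return float(dx @ dy / denom)


def one_sample_t(values, mu0: float = 0.0) -> GroupTestResult:
    """Two-sided one-sample t test of mean(values) against ``mu0``.

    t = (mean - mu0) / (sd / sqrt(n)) with the unbiased (n-1) standard
    deviation; df = n - 1.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        if mean == mu0:
            # all values sit exactly on the null: no evidence either way
            return GroupTestResult(0.0, n - 1, 1.0, mean, 0.0)
        raise ValueError("zero variance with mean off the null: t undefined")
    sem = sd / math.sqrt(n)
    t = (mean - mu0) / sem
    p = 2.0 * float(t_dist.sf(abs(t), n - 1))
    return GroupTestResult(float(t), n - 1, min(p, 1.0), mean, sem)


def paired_t(a, b) -> GroupTestResult:
    """Paired t test: one-sample t of the differences a - b against 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, mu0=0.0)
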