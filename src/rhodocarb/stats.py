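"""Nonparametric inference used for the vial experiment, from first principles.

Kruskal–Wallis on mid-ranks with the standard tie correction, Dunn's
post-hoc z-tests with the Šidák family-wise adjustment, and Pearson
correlation with the t-distribution p-value.  Only ranking and the reference
distributions (chi-square, normal, t) come from scipy; the statistics
themselves are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "GroupSeries",
    "KruskalResult",
    "kruskal_wallis",
    "dunn_sidak",
    "pearson",
    "sidak_adjust",
]


@dataclass(frozen=True)
class GroupSeries:
    """Measurements split into labelled groups (>= 2 groups, each n >= 2)."""

    labels: tuple
    groups: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.groups):
            raise ValueError("labels and groups must align")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for lab, g in zip(self.labels, self.groups):
            if len(g) < 2:
                raise ValueError(f"group {lab!r} has n < 2")

    @classmethod
    def from_arrays(cls, *groups, labels: Sequence | None = None) -> "GroupSeries":
        labels = tuple(labels) if labels is not None else tuple(range(len(groups)))
        return cls(labels=labels, groups=tuple(np.asarray(g, float) for g in groups))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value: str, by: Sequence[str] | str
    ) -> "GroupSeries":
        by = [by] if isinstance(by, str) else list(by)
        labels, groups = [], []
        for key, sub in df.groupby(by, sort=True):
            labels.append(key if len(by) > 1 else (key,))
            groups.append(sub[value].to_numpy(float))
        return cls(labels=tuple(labels), groups=tuple(groups))


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    pvalue: float
    tie_correction: float


def _pooled_ranks(series: GroupSeries):
    values = np.concatenate(series.groups)
    ranks = rankdata(values)  # mid-ranks for ties
    sizes = np.array([len(g) for g in series.groups])
    return values, ranks, sizes


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(series: GroupSeries) -> KruskalResult:
    """H statistic on mid-ranks with tie correction; p from chi-square(k-1).

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N).
    """
    values, ranks, sizes = _pooled_ranks(series)
    n_total = len(values)
    bounds = np.cumsum(sizes)
    mean_ranks = np.array(
        [r.mean() for r in np.split(ranks, bounds[:-1])]
    )
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(
        sizes * (mean_ranks - (n_total + 1) / 2.0) ** 2
    )
    correction = 1.0 - _tie_term(values) / (n_total**3 - n_total)
    if correction == 0:  # every value identical: no information, H defined as 0
        return KruskalResult(0.0, len(sizes) - 1, 1.0, 0.0)
    h /= correction
    df = len(sizes) - 1
    return KruskalResult(float(h), df, float(chi2.sf(h, df)), float(correction))


def sidak_adjust(p_raw: float | np.ndarray, m: int) -> float | np.ndarray:
    """Šidák family-wise adjustment over ``m`` comparisons: 1 - (1-p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p_raw)) ** m


def dunn_sidak(series: GroupSeries) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests with Šidák-adjusted p-values.

    z_ij = (Rbar_i - Rbar_j) / sqrt(V (1/n_i + 1/n_j)) with the tie-corrected
    pooled rank variance V = N(N+1)/12 - sum(t^3 - t)/(12(N-1)); the
    adjustment exponent m (all pairwise comparisons) is reported per row so
    the family size can be audited.
    """
    values, ranks, sizes = _pooled_ranks(series)
    n_total = len(values)
    bounds = np.cumsum(sizes)
    mean_ranks = np.array([r.mean() for r in np.split(ranks, bounds[:-1])])
    pooled_var = n_total * (n_total + 1) / 12.0 - _tie_term(values) / (
        12.0 * (n_total - 1)
    )
    k = len(sizes)
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(pooled_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = float(2.0 * norm.sf(abs(z)))
            rows.append(
                {
                    "group_i": series.labels[i],
                    "group_j": series.labels[j],
                    "mean_rank_i": float(mean_ranks[i]),
                    "mean_rank_j": float(mean_ranks[j]),
                    "z": float(z),
                    "p_raw": p_raw,
                    "p_adj": float(sidak_adjust(p_raw, m)),
                    "m": m,
                }
            )
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value (df n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = np.sum(dx * dx), np.sum(dy * dy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * t_dist.sf(abs(t), n - 2))
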