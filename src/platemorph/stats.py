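"""Validation and group-comparison statistics.

Pixel confusion / intersection-over-union for segmentation validation,
Bland-Altman limits of agreement and Pearson correlation for shape-
parameter agreement, and Dunn's rank-based test for non-parametric
multiple comparisons (mid-rank ties, tie-corrected variance, raw and
Holm-adjusted p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import BinaryMask, DegenerateInputError, ParameterError


@dataclass
class PixelConfusion:
    tp: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(tp, fp, fn) as fractions of their sum (sums to 1)."""
        t = self.total
        if t == 0:
            raise DegenerateInputError("both masks empty; confusion undefined")
        return self.tp / t, self.fp / t, self.fn / t

    @property
    def iou(self) -> float:
        t = self.total
        return self.tp / t if t else 1.0


@dataclass
class AgreementReport:
    mean_diff: float
    lower_limit: float
    upper_limit: float
    pearson_r: float | None
    means: np.ndarray
    diffs: np.ndarray


@dataclass
class DunnResult:
    """Pairwise comparison (i, j) from a Dunn's test."""

    group_i: int
    group_j: int
    z: float
    p_raw: float
    p_holm: float


def pixel_confusion(pred: BinaryMask, truth: BinaryMask) -> PixelConfusion:
    """Pixel-wise TP/FP/FN counts; true negatives excluded by construction."""
    if pred.shape != truth.shape:
        raise ParameterError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    p, t = pred.pixels, truth.pixels
    return PixelConfusion(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementReport:
    """Limits of agreement: mean difference +/- 1.96 * sample SD (n-1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    if len(x) < 2:
        raise ParameterError("need at least 2 pairs")
    d = x - y
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    r = None
    if len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        r = pearson_r(x, y)
    return AgreementReport(
        mean_diff=mean_d,
        lower_limit=mean_d - 1.96 * sd,
        upper_limit=mean_d + 1.96 * sd,
        pearson_r=r,
        means=(x + y) / 2.0,
        diffs=d,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or len(x) < 3:
        raise ParameterError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def dunns_test(groups: list[np.ndarray]) -> list[DunnResult]:
    """Dunn's test for non-parametric multiple comparisons.

    All observations are ranked jointly (mid-ranks for ties); for each
    pair of groups ``z = (mean-rank difference) / SE`` with the
    tie-corrected standard error.  Two-sided p-values are reported raw
    and Holm-adjusted over all pairs.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    for gi, g in enumerate(groups):
        if len(g) < 2:
            raise ParameterError(f"group {gi} has fewer than 2 observations")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start:start + len(g)])))
        start += len(g)

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            if se == 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            results.append(DunnResult(i, j, float(z), min(p, 1.0), np.nan))

    # Holm step-down adjustment over all pairs
    m = len(results)
    order = np.argsort([r.p_raw for r in results])
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * results[idx].p_raw
        running = max(running, adj)
        results[idx].p_holm = float(min(running, 1.0))
    return results
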