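"""Evaluation battery: ROC/AUC, non-parametric group tests, rmcorr, VI trend.

Discrimination is summarised by the area under the ROC curve (equivalently
the Mann-Whitney probability that a random high-vigilance epoch scores above
a random low-vigilance one, ties half-credited) and by the maximum
classification accuracy over all score thresholds.  Configuration
comparisons use the Kruskal-Wallis rank test with a Tukey HSD post-hoc on
rank means; paired contrasts use the Wilcoxon signed rank.  The link between
the vigilance index and behaviour is quantified with the repeated-measures
correlation (rmcorr): the common within-subject slope from an ANCOVA with
subject-specific intercepts, with dof = N_obs - N_subjects - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .model import VigilanceIndexSeries


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    max_accuracy: float
    best_threshold: float


@dataclass
class RmcorrResult:
    r: float
    dof: int
    p: float
    slope: float
    intercepts: dict

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")


@dataclass
class GroupComparison:
    statistic: float
    p: float
    posthoc_p: np.ndarray | None = None  # symmetric pairwise matrix


@dataclass
class BlockTrend:
    block_means: np.ndarray         # (subjects, blocks)
    mean_trajectory: np.ndarray     # (blocks,)
    slope: float                    # per block index
    contrast_statistic: float | None
    contrast_p: float | None


def roc_evaluate(scores: VigilanceIndexSeries | np.ndarray,
                 labels: np.ndarray) -> ROCResult:
    """ROC curve, trapezoidal AUC, and maximum accuracy of a score series.

    High vigilance is predicted when the score meets or exceeds a threshold;
    the threshold sweep for maximum accuracy covers midpoints between
    adjacent distinct scores plus sentinels beyond both extremes.
    """
    s = scores.vi if isinstance(scores, VigilanceIndexSeries) else np.asarray(scores)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to evaluate a ROC")

    fpr, tpr, thr = _skm.roc_curve(y, s)
    auc = float(_skm.auc(fpr, tpr))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pred = s[None, :] >= cands[:, None]
    acc = (pred == (y[None, :] == 1)).mean(axis=1)
    best = int(np.argmax(acc))
    return ROCResult(
        thresholds=thr, tpr=tpr, fpr=fpr, auc=auc,
        max_accuracy=float(acc[best]), best_threshold=float(cands[best]),
    )


def kruskal_wallis(groups: Sequence[np.ndarray]) -> GroupComparison:
    """Rank-based one-way comparison (tie-corrected H, chi-square p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all values identical across groups (degenerate ties)")
    stat, p = stats.kruskal(*groups)
    return GroupComparison(statistic=float(stat), p=float(p))


def tukey_posthoc(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Tukey HSD on rank-transformed data, matching the rank-based omnibus.

    Returns the symmetric pairwise p-value matrix with unit diagonal.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    sizes = [len(g) for g in groups]
    ranks = stats.rankdata(np.concatenate([np.asarray(g, float) for g in groups]))
    rank_groups = np.split(ranks, np.cumsum(sizes)[:-1])
    res = stats.tukey_hsd(*rank_groups)
    pmat = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(pmat, 1.0)
    return pmat


def wilcoxon_signed_rank(paired_a: np.ndarray, paired_b: np.ndarray,
                         alternative: str = "two-sided") -> tuple[float, float]:
    """Paired signed-rank test.

    Exact null distribution for n <= 25 non-zero differences, normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    n_nonzero = int(np.sum(diffs != 0))
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero")
    if n_nonzero < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    method = "exact" if n_nonzero <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative=alternative, method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative=alternative, method="approx")
    return float(res.statistic), float(res.pvalue)


def rmcorr(subject_ids: Sequence, x: np.ndarray, y: np.ndarray) -> RmcorrResult:
    """Repeated-measures correlation: common within-subject association.

    Fits y on x with subject-specific intercepts and one shared slope
    (ANCOVA); r carries the slope's sign and magnitude
    sqrt(SS_x / (SS_x + SS_error)); dof = N - k - 1 with k subjects.
    Subjects contributing fewer than 2 observations are dropped with a
    warning.
    """
    subjects = np.asarray(subject_ids)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (len(subjects) == len(x) == len(y)):
        raise ValueError("subject_ids, x and y must have equal length")

    uniq, counts = np.unique(subjects, return_counts=True)
    singles = uniq[counts < 2]
    if len(singles):
        warnings.warn(f"dropping {len(singles)} subject(s) with a single "
                      "observation", stacklevel=2)
        keep = ~np.isin(subjects, singles)
        subjects, x, y = subjects[keep], x[keep], y[keep]
        uniq = uniq[counts >= 2]
    k = len(uniq)
    n = len(x)
    if k < 2:
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 observations")

    dummies = (subjects[:, None] == uniq[None, :]).astype(float)
    full = np.column_stack([dummies, x])
    coef_full, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
    resid_full = y - full @ coef_full
    rss_full = float(resid_full @ resid_full)
    coef_red, _, _, _ = np.linalg.lstsq(dummies, y, rcond=None)
    resid_red = y - dummies @ coef_red
    rss_red = float(resid_red @ resid_red)

    ss_x = max(rss_red - rss_full, 0.0)
    slope = float(coef_full[-1])
    denom = ss_x + rss_full
    r = 0.0 if denom == 0 else math_copysign((ss_x / denom) ** 0.5, slope)
    dof = n - k - 1
    if dof <= 0:
        raise ValueError("not enough observations for rmcorr dof")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * (dof / (1.0 - r * r)) ** 0.5
        p = float(2.0 * stats.t.sf(abs(t), dof))
    intercepts = {subj: float(c) for subj, c in zip(uniq, coef_full[:-1])}
    return RmcorrResult(r=float(r), dof=int(dof), p=p, slope=slope,
                        intercepts=intercepts)


def math_copysign(mag: float, sign_src: float) -> float:
    return mag if sign_src >= 0 else -mag


def vi_trend(
    vi: Mapping[object, VigilanceIndexSeries] | VigilanceIndexSeries,
    block_boundaries: Sequence[float],
) -> BlockTrend:
    """Per-block mean VI, linear trend slope, first-vs-last block contrast.

    ``block_boundaries`` gives the b+1 time edges of b blocks.  With several
    subjects the first-vs-last contrast is a paired signed-rank across
    subjects (needs >= 5 subjects for a defined p-value); with a single
    series only means and slope are reported.
    """
    series = vi if isinstance(vi, Mapping) else {0: vi}
    bounds = np.asarray(block_boundaries, float)
    if len(bounds) < 3:
        raise ValueError("need at least 2 blocks")

    rows = []
    for _subject, s in series.items():
        means = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mask = (s.times >= lo) & (s.times < hi)
            if not mask.any():
                raise ValueError(f"empty VI block [{lo}, {hi})")
            means.append(float(s.vi[mask].mean()))
        rows.append(means)
    block_means = np.asarray(rows)
    trajectory = block_means.mean(axis=0)
    slope = float(np.polyfit(np.arange(len(trajectory)), trajectory, 1)[0])

    stat = p = None
    if block_means.shape[0] >= 5:
        first, last = block_means[:, 0], block_means[:, -1]
        if np.any(first != last):
            stat, p = wilcoxon_signed_rank(first, last)
    return BlockTrend(block_means=block_means, mean_trajectory=trajectory,
                      slope=slope, contrast_statistic=stat, contrast_p=p)
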