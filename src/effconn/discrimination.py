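"""Median-split group discrimination via ROC analysis.

Subjects are split into high/low inverse-efficiency groups at the sample
median; a nodal metric's ability to discriminate the groups is summarized
by the Mann–Whitney AUC with the Hanley–McNeil standard error, a normal
two-sided test against 0.5, and the Youden-optimal operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSplit:
    """Subject partition at the median IE (group sizes differ by <= 1)."""

    labels: np.ndarray  # "high" / "low" per subject
    median_ie: float

    @property
    def high(self) -> np.ndarray:
        return self.labels == "high"

    @property
    def low(self) -> np.ndarray:
        return self.labels == "low"


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    p: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    #: "high_scores_higher" or "low_scores_higher" (AUC reported >= 0.5)
    direction: str


def median_split(ie: np.ndarray) -> GroupSplit:
    """Split subjects at the median IE: above -> high, below -> low.

    Subjects exactly at the median are assigned low-first in stable subject
    order until the groups balance (a warning is emitted), so the result is
    deterministic and group sizes differ by at most one.
    """
    ie = np.asarray(ie, dtype=float)
    n = len(ie)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.isnan(ie).any():
        raise ValueError("IE contains NaN")
    if np.all(ie == ie[0]):
        raise ValueError("all IE values identical; median split undefined")
    med = float(np.median(ie))
    labels = np.empty(n, dtype=object)
    labels[ie > med] = "high"
    labels[ie < med] = "low"
    ties = np.flatnonzero(ie == med)
    if ties.size:
        warnings.warn(
            f"{ties.size} subject(s) exactly at the median; "
            "assigned low-first by subject order",
            stacklevel=2,
        )
        n_low_target = n - n // 2
        for t in ties:
            n_low = int((labels == "low").sum())
            labels[t] = "low" if n_low < n_low_target else "high"
    return GroupSplit(labels=labels.astype(str), median_ie=med)


def group_ttest(ie: np.ndarray, split: GroupSplit) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test between the IE groups.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    hi = np.asarray(ie, dtype=float)[split.high]
    lo = np.asarray(ie, dtype=float)[split.low]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both groups need at least 2 subjects")
    if np.var(hi, ddof=1) == 0 and np.var(lo, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(hi, lo, equal_var=True)
    return float(t), len(hi) + len(lo) - 2, float(p)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos == neg) over all pairs."""
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    """Standard error of the AUC (Hanley & McNeil 1982)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(
    scores: np.ndarray,
    split: GroupSplit,
    exact_p: bool = False,
) -> ROCResult:
    """ROC discrimination of the high vs low IE groups by one metric.

    The AUC is the Mann–Whitney probability (ties counted 0.5), oriented so
    AUC >= 0.5; the recorded ``direction`` says which group scores higher.
    The operating point maximizes Youden's J (ties -> lower threshold).
    ``exact_p`` swaps the Hanley–McNeil normal approximation for the exact
    Mann–Whitney test, useful at very small n.
    """
    scores = np.asarray(scores, dtype=float)
    hi = scores[split.high]
    lo = scores[split.low]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(scores == scores[0]):
        raise ValueError("degenerate single-valued scores")
    auc = _mann_whitney_auc(hi, lo)
    direction = "high_scores_higher"
    if auc < 0.5:
        auc = 1.0 - auc
        hi, lo = lo, hi
        direction = "low_scores_higher"
    n1, n2 = len(hi), len(lo)
    se = hanley_mcneil_se(auc, n1, n2)
    if exact_p:
        p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
    else:
        z = (auc - 0.5) / se if se > 0 else np.inf
        p = float(2 * stats.norm.sf(abs(z)))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # Youden-optimal threshold: classify "positive" (hi group) as score >= thr
    thresholds = np.unique(np.concatenate([hi, lo]))
    best_j, best = -np.inf, (thresholds[0], 0.0, 0.0)
    for thr in thresholds:  # ascending: ties resolved to the lower threshold
        sens = float((hi >= thr).mean())
        spec = float((lo < thr).mean())
        j = sens + spec - 1
        if j > best_j:
            best_j, best = j, (float(thr), sens, spec)
    threshold, sensitivity, specificity = best
    return ROCResult(
        auc=auc,
        se=se,
        p=p,
        ci95=ci,
        sensitivity=sensitivity,
        specificity=specificity,
        threshold=threshold,
        direction=direction,
    )
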