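"""Shared statistics: rank-based ROC/AUC and Student t group comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC classification of good (positive) vs poor outcome by a score.

    The AUC is computed with the rank (Mann-Whitney) formula with midranks
    for ties; curve points come from sweeping all thresholds.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass
class GroupCompareResult:
    t: float
    dof: int
    p: float
    mean_diff: float
    degenerate: bool = False


def group_compare(values_a: Sequence[float], values_b: Sequence[float],
                  paired: bool = False) -> GroupCompareResult:
    """Two-sided Student t test between groups (paired or unpaired, equal var).

    Zero-variance situations (e.g. a constant paired difference) are flagged
    as degenerate rather than reported with an infinite statistic.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    mean_diff = float(a.mean() - b.mean())
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.isclose(d.std(ddof=1), 0.0):
            if np.isclose(mean_diff, 0.0):
                return GroupCompareResult(0.0, a.size - 1, 1.0, mean_diff, False)
            return GroupCompareResult(np.nan, a.size - 1, np.nan, mean_diff, True)
        t, p = sps.ttest_rel(a, b)
        dof = a.size - 1
    else:
        if np.isclose(a.std(ddof=1), 0.0) and np.isclose(b.std(ddof=1), 0.0):
            if np.isclose(mean_diff, 0.0):
                return GroupCompareResult(0.0, a.size + b.size - 2, 1.0,
                                          mean_diff, False)
            return GroupCompareResult(np.nan, a.size + b.size - 2, np.nan,
                                      mean_diff, True)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        dof = a.size + b.size - 2
    return GroupCompareResult(float(t), int(dof), float(p), mean_diff, False)
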