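"""Benchmarking statistics: ROC/AUC, one-sided Mann–Whitney, one-sided
hypergeometric overlap, and Spearman rank agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

#: combined sample size at or below which the Mann–Whitney p is exact
EXACT_MWU_N = 20


@dataclass(frozen=True)
class RocResult:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the trapezoidal AUC.

    The trapezoid across tied scores counts tied pairs as 1/2, so
    AUC = U / (n_pos * n_neg) exactly.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    alternative: str = "positives stochastically larger"


@dataclass(frozen=True)
class OverlapTestResult:
    overlap: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float
    alternative: str = "overlap at least as large as observed"


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for binary labels (1 = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def mann_whitney_one_sided(group_pos, group_neg) -> MannWhitneyResult:
    """One-sided Wilcoxon–Mann–Whitney test (positives larger).

    Exact enumeration for combined n <= 20 without ties; the
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(group_pos, dtype=float)
    y = np.asarray(group_neg, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = (x.size + y.size) <= EXACT_MWU_N and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="greater",
                             method="exact" if exact else "asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             method="exact" if exact else "asymptotic")


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapTestResult:
    """One-sided hypergeometric test for set overlap enrichment."""
    a, b, u = set(set_a), set(set_b), set(universe)
    offenders = (a | b) - u
    if offenders:
        raise ValueError(f"sets not contained in universe: {sorted(offenders)}")
    k = len(a & b)
    # upper tail: P(overlap >= k) drawing |A| from a universe with |B| marked
    p = float(stats.hypergeom.sf(k - 1, len(u), len(b), len(a)))
    return OverlapTestResult(overlap=k, size_a=len(a), size_b=len(b),
                             universe_size=len(u), p_value=min(p, 1.0))


def spearman_agreement(rank_a, rank_b) -> tuple[float, float]:
    """Spearman rho between two gene rankings over their shared universe.

    Accepts :class:`~netmias.network.RankedList` objects or score Series;
    two-sided p via the t approximation.
    """
    sa = rank_a.scores if hasattr(rank_a, "scores") else pd.Series(rank_a)
    sb = rank_b.scores if hasattr(rank_b, "scores") else pd.Series(rank_b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    rho, p = stats.spearmanr(sa.loc[shared], sb.loc[shared])
    return float(rho), float(p)
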