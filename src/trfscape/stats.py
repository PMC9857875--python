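"""Shared statistical kernels.

Every hypothesis test used across the pipeline goes through this module so
that the conventions (two-sidedness, tie handling, no continuity correction
on chi-squared, Benjamini-Hochberg step-up) are decided exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "rank_sum_test",
    "kruskal_test",
    "chi2_test",
    "contingency_summary",
    "ROCResult",
    "roc_auc",
    "significance_stars",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sample unpaired Wilcoxon rank-sum test, two-sided.

    Uses the exact null distribution when both samples are small and
    tie-free, and the tie-corrected normal approximation otherwise
    (scipy's ``method="auto"`` rule).  Returns ``(statistic, p)`` where the
    statistic is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def kruskal_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction over >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def chi2_test(table, exact: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    ``exact=True`` switches to Fisher's exact test for 2x2 tables and to a
    Monte-Carlo permutation estimate of the exact p for larger tables
    (useful when expected cell counts are small).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if exact:
        if t.shape == (2, 2):
            _, p = sps.fisher_exact(t)
            return float("nan"), float(p)
        stat, p = _permutation_chi2(t)
        return stat, p
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _permutation_chi2(table: np.ndarray, n_perm: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo p-value for the chi-squared statistic with margins fixed."""
    rng = np.random.default_rng(seed)
    obs_stat, _, _, _ = sps.chi2_contingency(table, correction=False)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        s, _, _, _ = sps.chi2_contingency(t, correction=False)
        hits += s >= obs_stat - 1e-12
    return float(obs_stat), (hits + 1) / (n_perm + 1)


def contingency_summary(table: pd.DataFrame, exact: bool = False) -> dict:
    """Summarize a levels x groups count table.

    Returns the chi-squared statistic and p-value plus, per group, the
    percentage of each level within the group (the presentation used for
    clinicopathological and driver-event tables).
    """
    stat, p = chi2_test(table.values, exact=exact)
    col_totals = table.sum(axis=0)
    pct = table.div(col_totals, axis=1) * 100.0
    return {
        "statistic": stat,
        "p_value": p,
        "counts": table,
        "percent": pct,
        "group_totals": col_totals,
    }


@dataclass
class ROCResult:
    """Empirical ROC curve and its trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # true-positive rate, per threshold
    specificity: np.ndarray  # 1 - false-positive rate, per threshold
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of a continuous score against binary labels.

    The AUC is the trapezoidal area over the empirical ROC with ties
    grouped, which equals the Mann-Whitney convention
    U / (n1 * n0) with ties counted 1/2.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def significance_stars(p: float) -> str:
    """Figure-style significance annotation for a p-value."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
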