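"""Differential expression, classifier feature selection, and
guilt-by-association co-expression.

Tumor-vs-normal differential expression uses the two-sample unpaired
Wilcoxon rank-sum test with Benjamini-Hochberg correction; a 5'-tRF is
called differential at FDR < 0.01 and |log2FC| > 1, where log2FC is the
difference of group means on the log2-normalized scale (a ratio-of-means
alternative is available).  Guilt-by-association screens Pearson
correlations between dysregulated tRFs and mRNA genes, keeping pairs with
|r| > 0.3 at FDR < 0.05 (BH applied jointly over all pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .matrix import ExpressionMatrix
from .quant import filter_detected

logger = logging.getLogger(__name__)


def filter_mrna(
    matrix: ExpressionMatrix, quantile: float = 0.90, threshold: float = 1.0
) -> ExpressionMatrix:
    """Drop low-expressed genes (q-th quantile RPKM < threshold) and
    log2(v+1)-transform the remainder."""
    kept = filter_detected(matrix, quantile=quantile, threshold=threshold)
    return ExpressionMatrix(np.log2(kept.data + 1.0), scale="log2")


def wilcoxon_de(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    fdr_max: float = 0.01,
    min_abs_log2fc: float = 1.0,
    fc_mode: str = "mean-difference",
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal rank-sum tests with BH correction.

    Returns a DataFrame indexed by feature id with columns log2FC,
    p_value, fdr, mean_tumor, mean_normal and direction (up/down/ns at
    the stated thresholds).  ``fc_mode="mean-ratio"`` instead computes
    log2 of the ratio of linear-scale group means.
    """
    groups = labels.reindex(matrix.sample_ids)
    tumor_ids = groups.index[groups == "tumor"]
    normal_ids = groups.index[groups == "normal"]
    if len(tumor_ids) == 0 or len(normal_ids) == 0:
        raise ValueError("both tumor and normal groups must be non-empty")
    tum = matrix.data[tumor_ids].to_numpy(dtype=float)
    nor = matrix.data[normal_ids].to_numpy(dtype=float)
    mean_t = tum.mean(axis=1)
    mean_n = nor.mean(axis=1)
    if fc_mode == "mean-difference":
        log2fc = mean_t - mean_n
    elif fc_mode == "mean-ratio":
        log2fc = np.log2(np.exp2(tum).mean(axis=1) / np.exp2(nor).mean(axis=1))
    else:
        raise ValueError("fc_mode must be 'mean-difference' or 'mean-ratio'")
    pvals = np.empty(len(matrix.feature_ids))
    for i in range(len(pvals)):
        _, pvals[i] = stats.rank_sum_test(tum[i], nor[i])
    fdr = stats.bh_adjust(pvals)
    direction = np.where(
        (fdr < fdr_max) & (np.abs(log2fc) > min_abs_log2fc),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "direction": direction,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )


def select_classifier_features(
    de_results: pd.DataFrame,
    k: int = 13,
    min_log2fc: float = 2.0,
    fdr_max: float = 0.01,
) -> list[str]:
    """Top-k most upregulated features with log2FC > 2 at FDR < 0.01.

    Ranked by log2FC descending, ties broken by smaller FDR then
    lexicographic id.  Returns all qualifying features (with a warning)
    when fewer than k qualify.
    """
    qual = de_results[
        (de_results["log2FC"] > min_log2fc) & (de_results["fdr"] < fdr_max)
    ].copy()
    qual = qual.reset_index().sort_values(
        by=["log2FC", "fdr", "feature_id"], ascending=[False, True, True]
    )
    ids = qual["feature_id"].tolist()
    if len(ids) < k:
        logger.warning("only %d features qualify (requested %d)", len(ids), k)
        return ids
    return ids[:k]


@dataclass
class CoexpressionPair:
    trf_id: str
    gene_id: str
    r: float
    p_value: float
    fdr: float


def gba_coexpression(
    trf_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    trf_ids: list[str] | None = None,
    r_min: float = 0.3,
    fdr_max: float = 0.05,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson co-expression screen between tRFs and mRNA genes.

    Computes r and the two-sided t-based p for every (tRF, gene) pair over
    the shared samples (by default all columns common to both matrices;
    pass tumor sample ids to restrict), applies BH jointly over all pairs,
    and returns pairs with |r| > r_min and FDR < fdr_max.
    """
    shared = [s for s in trf_matrix.sample_ids if s in set(mrna_matrix.sample_ids)]
    if samples is not None:
        shared = [s for s in shared if s in set(samples)]
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    trf_ids = list(trf_ids) if trf_ids is not None else trf_matrix.feature_ids
    T = trf_matrix.data.loc[trf_ids, shared].to_numpy(dtype=float)
    G = mrna_matrix.data[shared].to_numpy(dtype=float)
    Tz = T - T.mean(axis=1, keepdims=True)
    Gz = G - G.mean(axis=1, keepdims=True)
    Tn = np.sqrt((Tz**2).sum(axis=1))
    Gn = np.sqrt((Gz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Tz @ Gz.T) / np.outer(Tn, Gn)
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    fdr = stats.bh_adjust(p.ravel()).reshape(p.shape)
    keep = (np.abs(r) > r_min) & (fdr < fdr_max)
    ti, gi = np.where(keep)
    genes = mrna_matrix.feature_ids
    return pd.DataFrame(
        {
            "trf_id": [trf_ids[i] for i in ti],
            "gene_id": [genes[j] for j in gi],
            "r": r[ti, gi],
            "p_value": p[ti, gi],
            "fdr": fdr[ti, gi],
        }
    )
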