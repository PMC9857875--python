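"""Expression subtype discovery.

Samples are clustered by non-negative matrix factorization (Frobenius
objective, multiplicative updates) of a non-negative log2(RPM+1) matrix
restricted to variable features (IQR >= 0.5).  For each candidate rank k
the factorization is restarted from seeded random initializations, and a
restart-consensus matrix summarizes co-clustering stability; the rank is
chosen by the maximum cophenetic correlation coefficient of the
consensus (ties to the smaller k), with the dispersion coefficient
reported alongside.  Consensus K-means clustering over subsampled sample
sets corroborates the NMF partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from . import stats
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def iqr_filter(matrix: ExpressionMatrix, min_iqr: float = 0.5) -> ExpressionMatrix:
    """Keep features with across-sample interquartile range >= min_iqr
    (quartiles by linear interpolation; boundary inclusive)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    q3 = matrix.data.quantile(0.75, axis=1)
    q1 = matrix.data.quantile(0.25, axis=1)
    keep = (q3 - q1) >= min_iqr
    return ExpressionMatrix(matrix.data.loc[keep[keep].index], matrix.scale)


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

def nmf_multiplicative(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 2000,
    tol: float = 1e-5,
    stationarity_window: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frobenius-objective NMF by multiplicative updates.

    Iteration stops when the sample cluster assignment (argmax of the
    coefficient columns) has been stationary for ``stationarity_window``
    iterations (checked every 10, the canonical consensus-NMF stopping
    rule — it preserves the restart-to-restart variability that drives
    consensus rank selection), when the relative per-iteration objective
    decrease falls below ``tol``, or at ``max_iter``.  Returns
    (W, H, error_trace); the per-iteration Frobenius error is
    non-increasing (a property of the updates).
    """
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    m, n = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(1e-4, 1.0, size=(m, k)) * scale
    H = rng.uniform(1e-4, 1.0, size=(k, n)) * scale
    eps = 1e-10
    trace = [np.linalg.norm(V - W @ H, "fro")]
    labels = H.argmax(axis=0)
    stationary_since = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(V - W @ H, "fro")
        trace.append(err)
        if (trace[-2] - err) / max(trace[-2], eps) < tol:
            break
        if it % 10 == 0:
            new_labels = H.argmax(axis=0)
            if np.array_equal(new_labels, labels):
                if it - stationary_since >= stationarity_window:
                    break
            else:
                labels = new_labels
                stationary_since = it
    return W, H, np.asarray(trace)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between consensus dissimilarities and the cophenetic
    distances of their average-linkage dendrogram (1.0 for an exact
    block-diagonal consensus)."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if condensed.std() == 0:
        return 1.0
    Z = linkage(condensed, method="average")
    c, _ = cophenet(Z, condensed)
    return float(c)


def dispersion_coefficient(consensus: np.ndarray) -> float:
    """Mean of 4*(c - 0.5)^2 over consensus entries; 1.0 when every entry
    is exactly 0 or 1."""
    return float(np.mean(4.0 * (consensus - 0.5) ** 2))


@dataclass
class NMFRun:
    """NMF restarts at one rank with their consensus summary."""

    k: int
    basis: np.ndarray  # features x k, best restart
    coefficients: np.ndarray  # k x samples, best restart
    error_trace: np.ndarray
    consensus: np.ndarray
    cophenetic: float
    dispersion: float
    labels: pd.Series


#: Cophenetic coefficients within this distance of the maximum are treated
#: as ties (resolved toward the smaller rank).  The coefficient is
#: estimated from a finite set of restarts, so differences at this scale
#: are sampling noise, and an exact-equality tie rule would never fire.
COPHENETIC_TIE_TOL = 1e-3


def nmf_cluster(
    matrix: ExpressionMatrix,
    k_range: range | tuple[int, ...] = range(2, 8),
    restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-5,
    seed: int = 0,
) -> tuple[dict[int, NMFRun], int]:
    """NMF consensus clustering over a range of ranks.

    Returns per-rank results and the selected k (cophenetic maximum,
    ties broken toward the smaller k; coefficients within
    ``COPHENETIC_TIE_TOL`` of the maximum count as tied).  The restart
    consensus uses stationarity-stopped runs; the reported factors and
    hard labels come from the best restart polished to objective
    convergence.  Ranks >= min(matrix dims) are skipped with a warning.
    """
    V = matrix.data.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    samples = matrix.sample_ids
    n = len(samples)
    runs: dict[int, NMFRun] = {}
    for k in k_range:
        if k >= min(V.shape):
            logger.warning("rank %d >= min matrix dimension; skipped", k)
            continue
        best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        co = np.zeros((n, n))
        for r in range(restarts):
            rng = np.random.default_rng([seed, k, r])
            W, H, trace = nmf_multiplicative(V, k, rng, max_iter=max_iter, tol=tol)
            labels = H.argmax(axis=0)
            co += labels[:, None] == labels[None, :]
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace)
        consensus = co / restarts
        W, H, trace = best
        # polish the best restart to objective convergence for the final
        # factors; the consensus keeps the stationarity-stopped restarts
        eps = 1e-10
        polish = [trace[-1]]
        for _ in range(max_iter):
            H = H * ((W.T @ V) / (W.T @ W @ H + eps))
            W = W * ((V @ H.T) / (W @ (H @ H.T) + eps))
            err = np.linalg.norm(V - W @ H, "fro")
            polish.append(err)
            if (polish[-2] - err) / max(polish[-2], eps) < tol:
                break
        trace = np.concatenate([trace, polish[1:]])
        # subtype membership from the restart consensus (average-linkage
        # cut at k): single-restart argmax labels are unstable when the
        # objective has several near-optimal factorizations
        d = 1.0 - consensus
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
        hard = fcluster(Z, t=k, criterion="maxclust")
        runs[k] = NMFRun(
            k=k,
            basis=W,
            coefficients=H,
            error_trace=trace,
            consensus=consensus,
            cophenetic=cophenetic_coefficient(consensus),
            dispersion=dispersion_coefficient(consensus),
            labels=pd.Series(
                [f"tF-{c}" for c in hard], index=samples, name="subtype"
            ),
        )
    if not runs:
        raise ValueError("no feasible rank in k_range")
    best_coph = max(r.cophenetic for r in runs.values())
    selected = min(k for k, r in runs.items() if r.cophenetic >= best_coph - COPHENETIC_TIE_TOL)
    return runs, selected


# ---------------------------------------------------------------------------
# consensus K-means
# ---------------------------------------------------------------------------

@dataclass
class ConsensusClusterRun:
    k: int
    subsample: float
    reps: int
    consensus: np.ndarray
    labels: pd.Series


def consensus_kmeans(
    matrix: ExpressionMatrix,
    k: int,
    subsample: float = 0.8,
    reps: int = 1000,
    seed: int = 0,
) -> ConsensusClusterRun:
    """Consensus clustering: repeated Euclidean K-means over subsampled
    sample sets; the consensus entry for a pair is its co-clustering
    frequency among repetitions where both were sampled.  Final labels
    come from average-linkage hierarchical clustering of 1 - consensus."""
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    X = matrix.data.T.to_numpy(dtype=float)  # samples x features
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng([seed, 1])
    m = max(k, int(round(subsample * n)))
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for r in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(X[idx])
        co_sampled[np.ix_(idx, idx)] += 1
        same = lab[:, None] == lab[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    hard = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(
        [f"cc-{c}" for c in hard], index=matrix.sample_ids, name="subtype"
    )
    return ConsensusClusterRun(
        k=k, subsample=subsample, reps=reps, consensus=consensus, labels=labels
    )


# ---------------------------------------------------------------------------
# subtype-clinical associations
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = ("age", "psa", "gleason")
CATEGORICAL_VARS = ("grade_group",)


def subtype_association_tests(
    labels: pd.Series,
    clinical: pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_VARS,
    categorical: tuple[str, ...] = CATEGORICAL_VARS,
) -> pd.DataFrame:
    """Association of subtype labels with clinical variables.

    Continuous/ordinal variables use Kruskal-Wallis (tie-corrected);
    categorical variables use Pearson chi-squared without continuity
    correction; survival endpoints (``pfs``/``dfs`` when present) use the
    multi-group log-rank test.  Empty strata are excluded with a warning.
    """
    shared = labels.index.intersection(clinical.index)
    lab = labels.loc[shared]
    groups = [g for g in sorted(lab.unique()) if (lab == g).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty subtypes")
    rows = []
    for var in continuous:
        if var not in clinical.columns:
            continue
        vals = [clinical.loc[shared][lab == g][var].dropna().to_numpy() for g in groups]
        keep = [v for v in vals if len(v) > 0]
        if len(keep) < len(vals):
            logger.warning("%s: empty stratum excluded", var)
        stat, p = stats.kruskal_test(keep)
        rows.append({"variable": var, "test": "kruskal-wallis", "statistic": stat, "p_value": p})
    for var in categorical:
        if var not in clinical.columns:
            continue
        table = pd.crosstab(clinical.loc[shared][var], lab)
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
        stat, p = stats.chi2_test(table.values)
        rows.append({"variable": var, "test": "chi-squared", "statistic": stat, "p_value": p})
    for endpoint in ("pfs", "dfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if tcol in clinical.columns and ecol in clinical.columns:
            from lifelines.statistics import multivariate_logrank_test

            res = multivariate_logrank_test(
                clinical.loc[shared][tcol], lab, clinical.loc[shared][ecol]
            )
            rows.append(
                {
                    "variable": endpoint,
                    "test": "log-rank",
                    "statistic": float(res.test_statistic),
                    "p_value": float(res.p_value),
                }
            )
    return pd.DataFrame(rows).set_index("variable")
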