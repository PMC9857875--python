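"""Diagnostic classifiers: tumor vs normal on selected 5'-tRFs.

Four scorers mirror the field's standard toolbox — random forest (500
trees, sqrt(p) features per split), RBF-kernel SVM (cost 1, standardized
inputs, decision values as scores), logistic regression with a negligible
ridge (so separable data converge), and PLS discriminant analysis with 2
components.  Samples are split stratified 70/30; AUCs are reported on the
held-out split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .matrix import ExpressionMatrix
from .stats import ROCResult, roc_auc

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("RF", "SVM", "GLM", "PLS")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_samples(labels: pd.Series, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Stratified random train/test split of sample ids, deterministic
    given the seed."""
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    train, test = train_test_split(
        labels.index.to_numpy(),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels.to_numpy() if spec.stratified else None,
    )
    return list(train), list(test)


class _PLSDiscriminant:
    """PLS regression on a 0/1 response used as a discriminant scorer."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        ncomp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.model_ = PLSRegression(n_components=ncomp)
        self.model_.fit(X, np.asarray(y, dtype=float))
        return self

    def decision_function(self, X):
        return self.model_.predict(X).ravel()


def train_classifiers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    train_ids: list[str],
    seed: int = 0,
) -> dict[str, object]:
    """Fit the four scorers on the training samples.

    ``matrix`` is features x samples (restricted to the selected
    classifier features); zero-variance features in the training split are
    dropped with a warning.  Each returned scorer exposes
    ``decision_function(X)`` on a samples x features array ordered like
    ``matrix.feature_ids`` (minus dropped features, recorded on the dict).
    """
    y = (labels.loc[train_ids] == "tumor").astype(int).to_numpy()
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X = matrix.data[train_ids].T.to_numpy(dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
    X = X[:, keep]
    features = [f for f, k in zip(matrix.feature_ids, keep) if k]

    rf = RandomForestClassifier(
        n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
    ).fit(X, y)
    svm = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0)).fit(X, y)
    glm = make_pipeline(
        StandardScaler(), LogisticRegression(C=1e4, max_iter=5000)
    ).fit(X, y)
    pls = _PLSDiscriminant(n_components=2).fit(X, y)

    class _ProbaScorer:
        def __init__(self, model):
            self.model = model

        def decision_function(self, X):
            return self.model.predict_proba(X)[:, 1]

    return {
        "RF": _ProbaScorer(rf),
        "SVM": svm,
        "GLM": glm,
        "PLS": pls,
        "features": features,
        "hyperparameters": {
            "RF": {"n_estimators": 500, "max_features": "sqrt"},
            "SVM": {"kernel": "rbf", "C": 1.0, "scaled": True},
            "GLM": {"model": "logistic", "C": 1e4},
            "PLS": {"n_components": 2},
        },
    }


def evaluate_classifiers(
    scorers: dict,
    matrix: ExpressionMatrix,
    labels: pd.Series,
    test_ids: list[str],
) -> dict[str, ROCResult]:
    """Held-out ROC/AUC per scorer (test ids must be disjoint from train)."""
    X = matrix.data.loc[scorers["features"], test_ids].T.to_numpy(dtype=float)
    y = (labels.loc[test_ids] == "tumor").astype(int).to_numpy()
    out = {}
    for name in CLASSIFIER_NAMES:
        scores = scorers[name].decision_function(X)
        out[name] = roc_auc(scores, y)
    return out


def diagnose(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    feature_ids: list[str],
    spec: SplitSpec | None = None,
) -> pd.DataFrame:
    """End-to-end: split, train the four scorers, report held-out AUCs."""
    spec = spec or SplitSpec()
    sub = matrix.subset_features(feature_ids)
    train_ids, test_ids = split_samples(labels, spec)
    assert not set(train_ids) & set(test_ids)
    scorers = train_classifiers(sub, labels, train_ids, seed=spec.seed)
    rocs = evaluate_classifiers(scorers, sub, labels, test_ids)
    return pd.DataFrame(
        {
            "model": list(rocs),
            "auc": [r.auc for r in rocs.values()],
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "seed": spec.seed,
        }
    )
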