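"""Joint decision-vector encoding and the cross-validated AUC objective.

A single gene vector in the unit box [0, 1]^(n_features + 4) encodes, at
once, one importance weight per feature and the four classifier
hyperparameters (logistic-stage regularization strength and penalty type,
residual-stage SVM penalty C and RBF gamma).  The swarm optimizers search
this box; the objective is the mean stratified cross-validated ROC-AUC of
the residual-fusion classifier fitted from the decoded vector.

Continuous hyperparameter genes map to [0.01, 100] on a log10 scale
(these are scale parameters spanning four decades); the penalty gene splits
at 0.5, with >= 0.5 meaning L2.  Features are z-score standardized before
weighting — estimated on training folds only — so a weight measures
importance rather than units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizers import SearchSpace
from .synth import CohortTable

__all__ = [
    "N_HYPER_GENES",
    "FeatureWeights",
    "SafwreHyperparams",
    "Standardizer",
    "make_search_space",
    "decode_vector",
    "apply_feature_weights",
    "stratified_fold_ids",
    "cv_auc_objective",
    "cv_fold_aucs",
]

N_HYPER_GENES = 4
_LOG_LOW, _LOG_SPAN = -2.0, 4.0  # 10**(-2) .. 10**2


@dataclass(frozen=True)
class FeatureWeights:
    weights: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.feature_names),):
            raise ValueError("one weight per feature is required")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


@dataclass(frozen=True)
class SafwreHyperparams:
    lr_C: float
    lr_penalty: str  # "l1" or "l2"
    svm_C: float
    svm_gamma: float


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring; constant columns get unit scale."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def make_search_space(n_features: int) -> SearchSpace:
    """Unit box over n_features weight genes + 4 hyperparameter genes."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return SearchSpace.unit_box(n_features + N_HYPER_GENES)


def _gene_to_log(g: float) -> float:
    return float(10.0 ** (_LOG_LOW + _LOG_SPAN * g))


def decode_vector(
    genes: np.ndarray, feature_names: list[str] | tuple[str, ...]
) -> tuple[FeatureWeights, SafwreHyperparams]:
    """Split a gene vector into feature weights and hyperparameters."""
    genes = np.asarray(genes, dtype=float)
    n_features = len(feature_names)
    if genes.shape != (n_features + N_HYPER_GENES,):
        raise ValueError(
            f"expected {n_features + N_HYPER_GENES} genes, got {genes.shape}"
        )
    bad = np.flatnonzero((genes < 0.0) | (genes > 1.0))
    if bad.size:
        raise ValueError(f"gene {bad[0]} = {genes[bad[0]]!r} outside [0, 1]")
    weights = FeatureWeights(genes[:n_features].copy(), tuple(feature_names))
    g_lr_c, g_penalty, g_svm_c, g_gamma = genes[n_features:]
    hp = SafwreHyperparams(
        lr_C=_gene_to_log(g_lr_c),
        lr_penalty="l2" if g_penalty >= 0.5 else "l1",
        svm_C=_gene_to_log(g_svm_c),
        svm_gamma=_gene_to_log(g_gamma),
    )
    return weights, hp


def apply_feature_weights(X: np.ndarray, w: FeatureWeights) -> np.ndarray:
    """Columnwise multiply a (standardized) matrix by the feature weights."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != w.weights.shape[0]:
        raise ValueError("column count does not match weight count")
    return X * w.weights


def stratified_fold_ids(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Content-canonical stratified fold assignment.

    Rows are first put in a canonical order (lexicographic over feature
    values) so the assignment — and hence the objective — is invariant to
    the row order of the input table; within each class the canonically
    ordered rows are shuffled with the fold seed and dealt round-robin.
    """
    n = len(y)
    if X.shape[1] == 0:
        order = np.arange(n)
    else:
        order = np.lexsort(tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)))
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    for cls in np.unique(y):
        members = order[y[order] == cls]
        members = members[rng.permutation(len(members))]
        fold[members] = np.arange(len(members)) % n_folds
    return fold


def cv_fold_aucs(
    genes: np.ndarray,
    cohort: CohortTable,
    n_folds: int = 5,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
    with_pr: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold (ROC-AUC, PR-AUC) of the residual-fusion model under the
    decoded gene vector.  Standardization is fit on each fold's training
    portion only.

    By default folds are derived from the columns with nonzero weight, so a
    feature weighted exactly zero gives the identical objective as deleting
    its column.  Pass ``fold_ids`` to pin one assignment across several
    evaluations (the top-k contribution analysis does this so its curve
    points share folds with the full-model objective).
    """
    from . import metrics as _metrics
    from . import model as _model

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = cohort.y
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")
    X = cohort.X
    weights, hp = decode_vector(genes, cohort.feature_names)
    if fold_ids is None:
        fold = stratified_fold_ids(X[:, weights.weights != 0.0], y, n_folds, seed)
    else:
        fold = np.asarray(fold_ids)
    roc, pr = np.empty(n_folds), np.empty(n_folds)
    for k in range(n_folds):
        test_mask = fold == k
        X_tr, y_tr = X[~test_mask], y[~test_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {k} has a single class; use fewer folds or re-stratify"
            )
        fitted = _model.fit_safwre_arrays(X_tr, y_tr, weights, hp)
        s = _model.predict_score(fitted, X_te)
        roc[k] = _metrics.roc_auc(y_te, s)
        pr[k] = _metrics.pr_auc(y_te, s) if with_pr else np.nan
    return roc, pr


def cv_auc_objective(
    genes: np.ndarray,
    cohort: CohortTable,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified-CV ROC-AUC — the quantity the optimizers maximize."""
    roc, _ = cv_fold_aucs(genes, cohort, n_folds=n_folds, seed=seed, with_pr=False)
    return float(roc.mean())
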