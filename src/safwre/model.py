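"""The residual-fusion classifier and the grid-searched baselines.

The classifier stacks two stages on weighted, standardized features:

1. a penalized *logistic* stage fits the binary impairment label and emits a
   class-1 probability p (the task is binary classification, and the
   penalty-type hyperparameter only makes sense for a penalized GLM — this
   is the central interpretive decision of the implementation);
2. the residuals r = y - p, which are continuous in (-1, 1), are fitted by
   an epsilon-insensitive support-vector regressor with an RBF kernel;
3. the final score is clip(p + r_hat, 0, 1), thresholded at 0.5 for a hard
   label.

If the residual stage predicts exactly zero, the fusion reduces to the
linear stage — the nonlinear stage only contributes where the linear stage
leaves structured error.

Both stages are fitted with scikit-learn but predict through their exported
parameters (coefficients; support vectors + dual coefficients), so a model
serialized to JSON reproduces its scores bit-exactly after reload.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC, SVR

from .objective import (
    FeatureWeights,
    SafwreHyperparams,
    Standardizer,
    apply_feature_weights,
    decode_vector,
    stratified_fold_ids,
)
from .synth import CohortTable

__all__ = [
    "LinearStage",
    "ResidualStage",
    "FittedSafwre",
    "BaselineSpec",
    "DEFAULT_GRIDS",
    "fit_linear_stage",
    "compute_residuals",
    "fit_residual_stage",
    "fit_safwre",
    "fit_safwre_arrays",
    "predict_score",
    "classify",
    "fit_baseline_grid",
    "fit_baseline_estimator",
    "baseline_scores",
    "save_model",
    "load_model",
]


@dataclass
class LinearStage:
    coefficients: np.ndarray
    intercept: float
    penalty: str
    C: float

    def predict_proba(self, Xw: np.ndarray) -> np.ndarray:
        z = Xw @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ResidualStage:
    """RBF support-vector regressor reduced to its dual form."""

    support_vectors: np.ndarray  # (n_sv, d); empty for a constant predictor
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    C: float
    gamma: float
    epsilon: float = 0.1

    def predict(self, Xw: np.ndarray) -> np.ndarray:
        if self.support_vectors.size == 0:
            return np.full(len(Xw), self.intercept)
        d2 = (
            np.sum(Xw**2, axis=1)[:, None]
            - 2.0 * Xw @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept


@dataclass
class FittedSafwre:
    standardizer: Standardizer
    weights: FeatureWeights
    linear: LinearStage
    residual: ResidualStage
    threshold: float = 0.5


def fit_linear_stage(
    Xw: np.ndarray, y: np.ndarray, hp: SafwreHyperparams
) -> LinearStage:
    """Penalized logistic fit on the weighted features.

    L2 uses lbfgs; L1 uses liblinear with a large intercept scaling so the
    intercept is effectively unpenalized (full L1 shrinkage then leaves the
    prevalence log-odds in the intercept).
    """
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if hp.lr_penalty == "l2":
        est = LogisticRegression(l1_ratio=0, C=hp.lr_C, solver="lbfgs", max_iter=5000)
    else:
        est = LogisticRegression(
            l1_ratio=1,
            C=hp.lr_C,
            solver="liblinear",
            intercept_scaling=100.0,
            max_iter=5000,
        )
    est.fit(Xw, y)
    n_iter = int(np.max(est.n_iter_))
    if n_iter >= 5000:
        raise RuntimeError(
            "logistic stage did not converge; increase C or max iterations"
        )
    return LinearStage(
        coefficients=est.coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        penalty=hp.lr_penalty,
        C=hp.lr_C,
    )


def compute_residuals(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """r_i = y_i - p_i, each in (-1, 1) for probabilities strictly inside (0, 1)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    return y - p


def fit_residual_stage(
    Xw: np.ndarray, r: np.ndarray, hp: SafwreHyperparams, epsilon: float = 0.1
) -> ResidualStage:
    """Epsilon-SVR with RBF kernel on (weighted features, linear residuals).

    All-equal residuals degenerate to a constant predictor.
    """
    r = np.asarray(r, dtype=float)
    if np.ptp(r) == 0.0:
        return ResidualStage(
            support_vectors=np.empty((0, Xw.shape[1])),
            dual_coef=np.empty(0),
            intercept=float(r[0]) if r.size else 0.0,
            C=hp.svm_C,
            gamma=hp.svm_gamma,
            epsilon=epsilon,
        )
    est = SVR(kernel="rbf", C=hp.svm_C, gamma=hp.svm_gamma, epsilon=epsilon)
    est.fit(Xw, r)
    return ResidualStage(
        support_vectors=est.support_vectors_.copy(),
        dual_coef=est.dual_coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        C=hp.svm_C,
        gamma=hp.svm_gamma,
        epsilon=epsilon,
    )


def fit_safwre_arrays(
    X: np.ndarray,
    y: np.ndarray,
    weights: FeatureWeights,
    hp: SafwreHyperparams,
    threshold: float = 0.5,
    epsilon: float = 0.1,
) -> FittedSafwre:
    """standardize -> weight -> linear stage -> residuals -> residual stage."""
    standardizer = Standardizer.fit(X)
    Xw = apply_feature_weights(standardizer.transform(X), weights)
    linear = fit_linear_stage(Xw, y, hp)
    p = linear.predict_proba(Xw)
    r = compute_residuals(y, p)
    residual = fit_residual_stage(Xw, r, hp, epsilon=epsilon)
    return FittedSafwre(standardizer, weights, linear, residual, threshold)


def fit_safwre(
    cohort: CohortTable, genes: np.ndarray, threshold: float = 0.5
) -> FittedSafwre:
    """Fit the full pipeline on a cohort from a raw decision vector."""
    weights, hp = decode_vector(genes, cohort.feature_names)
    return fit_safwre_arrays(cohort.X, cohort.y, weights, hp, threshold=threshold)


def predict_score(m: FittedSafwre, X: np.ndarray) -> np.ndarray:
    """Fused score clip(p_linear + r_hat, 0, 1) on raw (unstandardized) rows."""
    Xw = apply_feature_weights(m.standardizer.transform(np.asarray(X, dtype=float)), m.weights)
    p = m.linear.predict_proba(Xw)
    return np.clip(p + m.residual.predict(Xw), 0.0, 1.0)


def classify(m: FittedSafwre, X: np.ndarray) -> np.ndarray:
    """Hard label: 1 iff score >= threshold."""
    return (predict_score(m, X) >= m.threshold).astype(int)


# ---------------------------------------------------------------------------
# Grid-searched baselines (LR / SVM / gradient boosting)
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lr": {"C": [0.01, 0.1, 1.0, 10.0, 100.0], "penalty": ["l1", "l2"]},
    "svm": {"C": [0.01, 0.1, 1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "xgb": {
        "learning_rate": [0.01, 0.05, 0.1, 0.3, 0.5, 1.0],
        "max_depth": [1, 3, 5, 10, 20],
        "n_estimators": [10, 25, 50, 100],
    },
}


@dataclass
class BaselineSpec:
    model_kind: str  # "lr" | "svm" | "xgb"
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    best_params: dict | None = None
    cv_auc: float | None = None

    def __post_init__(self) -> None:
        self.model_kind = self.model_kind.lower()
        if self.model_kind not in ("lr", "svm", "xgb"):
            raise ValueError(f"unknown baseline kind {self.model_kind!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model_kind].items()}


def _make_estimator(kind: str, params: Mapping[str, Any]):
    if kind == "lr":
        penalty = params.get("penalty", "l2")
        if penalty == "l1":
            return LogisticRegression(
                l1_ratio=1, C=params.get("C", 1.0), solver="liblinear",
                intercept_scaling=100.0, max_iter=5000,
            )
        return LogisticRegression(
            l1_ratio=0, C=params.get("C", 1.0), solver="lbfgs", max_iter=5000
        )
    if kind == "svm":
        return SVC(
            kernel="rbf",
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
        )
    if kind == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            learning_rate=params.get("learning_rate", 0.1),
            max_depth=params.get("max_depth", 3),
            n_estimators=params.get("n_estimators", 50),
            tree_method="hist",
            n_jobs=1,
            random_state=0,
            verbosity=0,
        )
    raise ValueError(f"unknown baseline kind {kind!r}")


def _decision_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def fit_baseline_grid(
    cohort: CohortTable, spec: BaselineSpec, n_folds: int = 5, seed: int = 0
) -> BaselineSpec:
    """Exhaustive grid search scored by mean stratified-CV ROC-AUC.

    Each fold standardizes on its own training portion.  Ties keep the first
    grid cell in iteration order.
    """
    from . import metrics as _metrics

    if not spec.grid or any(len(v) == 0 for v in spec.grid.values()):
        raise ValueError("baseline grid must be non-empty")
    X, y = cohort.X, cohort.y
    fold = stratified_fold_ids(X, y, n_folds, seed)
    names = list(spec.grid)
    best_auc, best_params = -np.inf, None
    for combo in itertools.product(*(spec.grid[k] for k in names)):
        params = dict(zip(names, combo))
        aucs = []
        for k in range(n_folds):
            test = fold == k
            std = Standardizer.fit(X[~test])
            est = _make_estimator(spec.model_kind, params)
            est.fit(std.transform(X[~test]), y[~test])
            aucs.append(_metrics.roc_auc(y[test], _decision_scores(est, std.transform(X[test]))))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return BaselineSpec(spec.model_kind, spec.grid, best_params, best_auc)


def fit_baseline_estimator(cohort: CohortTable, kind: str, params: Mapping[str, Any]):
    """Fit a baseline on the whole cohort; returns (standardizer, estimator)."""
    std = Standardizer.fit(cohort.X)
    est = _make_estimator(kind, params)
    est.fit(std.transform(cohort.X), cohort.y)
    return std, est


def baseline_scores(std: Standardizer, est, X: np.ndarray) -> np.ndarray:
    return _decision_scores(est, std.transform(np.asarray(X, dtype=float)))


# ---------------------------------------------------------------------------
# JSON serialization (bit-exact round trip: predictions use only these fields)
# ---------------------------------------------------------------------------

def _model_to_dict(m: FittedSafwre) -> dict:
    return {
        "format": "safwre-model",
        "version": 1,
        "standardizer": {
            "mean": m.standardizer.mean.tolist(),
            "scale": m.standardizer.scale.tolist(),
        },
        "weights": {
            "weights": m.weights.weights.tolist(),
            "feature_names": list(m.weights.feature_names),
        },
        "linear": {
            "coefficients": m.linear.coefficients.tolist(),
            "intercept": m.linear.intercept,
            "penalty": m.linear.penalty,
            "C": m.linear.C,
        },
        "residual": {
            "support_vectors": m.residual.support_vectors.tolist(),
            "dual_coef": m.residual.dual_coef.tolist(),
            "intercept": m.residual.intercept,
            "C": m.residual.C,
            "gamma": m.residual.gamma,
            "epsilon": m.residual.epsilon,
        },
        "threshold": m.threshold,
    }


def save_model(m: FittedSafwre, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(m), indent=1))


def load_model(path: str | Path) -> FittedSafwre:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "safwre-model":
        raise ValueError(f"{path} is not a serialized model file")
    n_dim = len(doc["weights"]["weights"])
    sv = np.asarray(doc["residual"]["support_vectors"], dtype=float)
    if sv.size == 0:
        sv = sv.reshape(0, n_dim)
    return FittedSafwre(
        standardizer=Standardizer(
            mean=np.asarray(doc["standardizer"]["mean"], dtype=float),
            scale=np.asarray(doc["standardizer"]["scale"], dtype=float),
        ),
        weights=FeatureWeights(
            np.asarray(doc["weights"]["weights"], dtype=float),
            tuple(doc["weights"]["feature_names"]),
        ),
        linear=LinearStage(
            coefficients=np.asarray(doc["linear"]["coefficients"], dtype=float),
            intercept=float(doc["linear"]["intercept"]),
            penalty=doc["linear"]["penalty"],
            C=float(doc["linear"]["C"]),
        ),
        residual=ResidualStage(
            support_vectors=sv,
            dual_coef=np.asarray(doc["residual"]["dual_coef"], dtype=float),
            intercept=float(doc["residual"]["intercept"]),
            C=float(doc["residual"]["C"]),
            gamma=float(doc["residual"]["gamma"]),
            epsilon=float(doc["residual"]["epsilon"]),
        ),
        threshold=float(doc["threshold"]),
    )
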