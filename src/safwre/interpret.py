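"""Weight-based interpretability: ranking, top-k contribution, plateau rule.

The optimized per-feature weights double as importances.  Features are
ranked by weight; the top-k contribution curve re-evaluates the
cross-validated ROC/PR-AUC with all but the k highest-weighted features
zeroed out (hyperparameters frozen, fold split identical to the main
objective, so curve points are directly comparable); the selected feature
count is the smallest k after which no step improves ROC-AUC by more than
``epsilon`` (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objective import FeatureWeights, cv_fold_aucs, decode_vector, stratified_fold_ids
from .synth import CohortTable

__all__ = [
    "WeightRanking",
    "ContributionCurve",
    "rank_weights",
    "topk_contribution_curve",
    "select_top_features",
]


@dataclass
class WeightRanking:
    """Features sorted by descending weight; ties keep original feature order."""

    ordered: list[tuple[str, float]]
    rank_of: dict[str, int]  # feature name -> 0-based rank

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ordered]


@dataclass
class ContributionCurve:
    k: np.ndarray
    roc_auc_at_k: np.ndarray
    pr_auc_at_k: np.ndarray
    selected_k: int


def rank_weights(w: FeatureWeights) -> WeightRanking:
    order = np.argsort(-w.weights, kind="stable")
    ordered = [(w.feature_names[i], float(w.weights[i])) for i in order]
    return WeightRanking(ordered, {name: r for r, (name, _) in enumerate(ordered)})


def topk_contribution_curve(
    cohort: CohortTable,
    ranking: WeightRanking,
    genes: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    epsilon: float = 0.01,
) -> ContributionCurve:
    """ROC/PR-AUC as a function of the number of top-weighted features kept.

    For each k, weights outside the top k are zeroed (the weight genes are
    masked; hyperparameter genes untouched) and the cross-validated AUCs are
    recomputed with the same fold seed.  k = n_features reproduces the full
    objective exactly.
    """
    names = cohort.feature_names
    if set(ranking.names) != set(names):
        raise ValueError("ranking does not cover the cohort's features")
    genes = np.asarray(genes, dtype=float)
    n = len(names)
    col = {name: j for j, name in enumerate(names)}
    # pin the full-model fold split so every curve point is comparable
    weights, _ = decode_vector(genes, names)
    fold_ids = stratified_fold_ids(
        cohort.X[:, weights.weights != 0.0], cohort.y, n_folds, seed
    )
    roc_k, pr_k = np.empty(n), np.empty(n)
    for k in range(1, n + 1):
        keep = {col[name] for name in ranking.names[:k]}
        masked = genes.copy()
        for j in range(n):
            if j not in keep:
                masked[j] = 0.0
        roc, pr = cv_fold_aucs(masked, cohort, n_folds=n_folds, seed=seed, fold_ids=fold_ids)
        roc_k[k - 1], pr_k[k - 1] = roc.mean(), pr.mean()
    curve = ContributionCurve(np.arange(1, n + 1), roc_k, pr_k, selected_k=1)
    curve.selected_k = select_top_features(curve, epsilon=epsilon)
    return curve


def select_top_features(curve: ContributionCurve, epsilon: float = 0.01) -> int:
    """Smallest k such that every later step gains < epsilon ROC-AUC."""
    increments = np.diff(curve.roc_auc_at_k)
    for k in range(1, len(curve.roc_auc_at_k) + 1):
        if np.all(increments[k - 1:] < epsilon):
            return k
    return len(curve.roc_auc_at_k)
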