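"""Cross-validated evaluation and the binomial chance machinery.

Folds are assigned at the group (subject) level so that repeated
measurements of one subject never straddle the train/test split; with
singleton groups this reduces to plain k-fold. Performance is pooled
over out-of-fold predictions (accuracy, rank-based AUC). The chance
level of a balanced two-class task is the smallest accuracy a fair-coin
classifier exceeds with probability <= 5%, obtained from the cumulative
binomial distribution; two classifiers are compared with an exact
binomial (McNemar-style) test on their discordant predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import models
from .datasets import ConnectomeDataset

__all__ = [
    "FoldPlan",
    "CVResult",
    "BinomialBaseline",
    "make_fold_plan",
    "cross_validate",
    "binomial_cdf",
    "chance_baseline",
    "compare_classifiers",
    "auc",
]


@dataclass
class FoldPlan:
    """Group-to-fold assignment for grouped cross-validation."""

    n_folds: int
    assignment: dict
    seed: int

    def instance_folds(self, group_ids) -> np.ndarray:
        """Fold index per instance, via each instance's group."""
        return np.array([self.assignment[g] for g in group_ids], dtype=int)


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and summary scores."""

    predicted_labels: np.ndarray
    positive_probs: np.ndarray
    fold_indices: np.ndarray
    true_labels: np.ndarray
    accuracy: float
    auc: float


@dataclass
class BinomialBaseline:
    """Chance-level accuracy threshold for n two-class trials."""

    n: int
    k: int
    p: float
    threshold: float
    baseline_accuracy: float
    cdf_at_k: float


def make_fold_plan(group_ids, n_folds: int, seed: int) -> FoldPlan:
    """Shuffle the distinct groups by seed and deal them round-robin.

    Every group lands in exactly one fold; folds differ in size by at
    most one group. Raises if there are fewer groups than folds.
    """
    groups = list(dict.fromkeys(group_ids))  # unique, first-appearance order
    if len(groups) < n_folds:
        raise ValueError(f"{len(groups)} groups cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    assignment = {groups[g]: int(pos % n_folds) for pos, g in enumerate(order)}
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def cross_validate(
    model_config,
    dataset: ConnectomeDataset,
    fold_plan: FoldPlan,
    fit_predict=None,
) -> CVResult:
    """Train on each fold's complement and predict its instances.

    ``fit_predict`` may override the model machinery (for stubs or
    external classifiers): a callable
    ``(dataset, train_idx, test_idx, fold) -> (n_test, 2) probabilities``.
    By default each fold builds and trains a fresh model from
    ``model_config`` with a fold-specific seed offset.
    Accuracy and AUC are pooled over all out-of-fold predictions.
    """
    folds = fold_plan.instance_folds(dataset.group_ids)
    n = dataset.n_instances
    probs = np.full(n, np.nan)
    preds = np.full(n, -1, dtype=int)
    for fold in range(fold_plan.n_folds):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        if test_idx.size == 0:
            continue
        if np.unique(dataset.labels[train_idx]).size < 2:
            raise ValueError(f"training complement of fold {fold} has a single class")
        if fit_predict is not None:
            p = np.asarray(fit_predict(dataset, train_idx, test_idx, fold))
        else:
            cfg = replace(model_config, seed=model_config.seed + 1000 * (fold + 1))
            model = models.build(cfg)
            models.train(model, dataset, train_idx)
            p = models.predict_proba(model, dataset, test_idx)
        probs[test_idx] = p[:, 1]
        preds[test_idx] = p.argmax(axis=1)
    if np.isnan(probs).any():
        raise AssertionError("some instances were never predicted")
    truth = dataset.labels
    return CVResult(
        predicted_labels=preds,
        positive_probs=probs,
        fold_indices=folds,
        true_labels=truth.copy(),
        accuracy=float(np.mean(preds == truth)),
        auc=auc(probs, truth),
    )


def binomial_cdf(n: int, k: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return float(stats.binom.cdf(k, n, p))


def chance_baseline(n: int, threshold: float = 0.95, p: float = 0.5) -> BinomialBaseline:
    """Chance-level accuracy: k/n for the smallest k with CDF >= threshold."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(stats.binom.ppf(threshold, n, p))
    while binomial_cdf(n, k, p) < threshold:
        k += 1
    while k > 0 and binomial_cdf(n, k - 1, p) >= threshold:
        k -= 1
    return BinomialBaseline(
        n=n, k=k, p=p, threshold=threshold,
        baseline_accuracy=k / n, cdf_at_k=binomial_cdf(n, k, p),
    )


def compare_classifiers(pred_a, pred_b, truth) -> float:
    """Exact two-sided binomial test on discordant predictions.

    Considers only instances where exactly one classifier is correct
    and tests whether the split deviates from 50/50 (McNemar's exact
    test). Returns 1.0 when the classifiers never disagree in
    correctness.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("prediction/truth vectors have different lengths")
    correct_a = pred_a == truth
    correct_b = pred_b == truth
    discordant = correct_a != correct_b
    n_disc = int(discordant.sum())
    if n_disc == 0:
        return 1.0
    k = int((correct_a & discordant).sum())
    return float(stats.binomtest(k, n_disc, 0.5, alternative="two-sided").pvalue)


def auc(prob_positive, truth) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve."""
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    return float(roc_auc_score(truth, np.asarray(prob_positive, dtype=float)))
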