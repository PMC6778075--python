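"""Classification performance metrics: error rate, one-vs-all ROC and
precision-recall curves, and cross-validated aggregation.

Multi-class probabilities are scored one-vs-all: class c's probability
column is treated as a binary score against the indicator truth == c.  ROC
AUC uses trapezoidal integration; precision-recall area uses the step-wise
(non-interpolated) convention, i.e. average precision.  Mean AUCs are
unweighted means over classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc as _auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .core import PatchDataset, stratified_holdout
from .model import ModelConfig, TrainConfig, build_classifier, patches_to_array, train_classifier

__all__ = [
    "EvalResult",
    "error_rate",
    "roc_auc_one_vs_all",
    "precision_recall_one_vs_all",
    "cross_validate",
]

PR_AREA_CONVENTION = "stepwise"  # documented output-metadata convention


@dataclass
class EvalResult:
    """Aggregated metrics, per-fold and mean +/- sd."""

    fold_accuracies: list[float] = field(default_factory=list)
    fold_roc_aucs: list[float] = field(default_factory=list)
    fold_pr_aucs: list[float] = field(default_factory=list)
    per_class_roc_auc: dict[int, float] = field(default_factory=dict)
    per_class_pr_auc: dict[int, float] = field(default_factory=dict)
    pr_area_convention: str = PR_AREA_CONVENTION

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.fold_roc_aucs))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_aucs))


def error_rate(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Misclassified fraction."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    return float(np.mean(predicted != truth))


def _one_vs_all(scores: np.ndarray, truth: np.ndarray):
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.ndim != 2 or scores.shape[0] != truth.shape[0]:
        raise ValueError("scores must be N x M aligned with truth")
    return scores, truth


def roc_auc_one_vs_all(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], dict[int, float], float]:
    """Per-class ROC curves and AUCs plus the unweighted class-mean AUC.

    Returns ``(curves, aucs, mean_auc)`` where curves maps class -> (fpr,
    tpr).  Classes absent from the truth are skipped with a warning.
    """
    scores, truth = _one_vs_all(scores, truth)
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[int, float] = {}
    for c in range(scores.shape[1]):
        binary = (truth == c).astype(int)
        if binary.sum() == 0 or binary.sum() == len(binary):
            warnings.warn(f"class {c} absent (or exhaustive) in truth; skipped", stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(binary, scores[:, c])
        curves[c] = (fpr, tpr)
        aucs[c] = float(_auc(fpr, tpr))
    mean_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return curves, aucs, mean_auc


def precision_recall_one_vs_all(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], dict[int, float], float]:
    """Per-class precision-recall curves with step-wise area (average
    precision), plus the unweighted class-mean area."""
    scores, truth = _one_vs_all(scores, truth)
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[int, float] = {}
    for c in range(scores.shape[1]):
        binary = (truth == c).astype(int)
        if binary.sum() == 0:
            warnings.warn(f"class {c} absent from truth; skipped", stacklevel=2)
            continue
        precision, recall, _ = precision_recall_curve(binary, scores[:, c])
        curves[c] = (recall, precision)
        aucs[c] = float(average_precision_score(binary, scores[:, c]))
    mean_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return curves, aucs, mean_auc


def cross_validate(
    dataset: PatchDataset,
    k: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    T: int = 50,
    class_restriction: list[int] | None = None,
) -> EvalResult:
    """Train/evaluate on each of k seeded stratified holdout splits.

    ``class_restriction`` first narrows the dataset to the given classes
    (relabelled 0..len-1), supporting e.g. the binary tumour-vs-stroma task.
    Test-set scores are T-sample MC predictive means.
    """
    if class_restriction is not None:
        dataset = dataset.restrict_classes(class_restriction)
        model_config = ModelConfig(
            n_classes=len(class_restriction),
            input_size=model_config.input_size,
            dropout_rate=model_config.dropout_rate,
            filters=model_config.filters,
            head_hidden_units=model_config.head_hidden_units,
        )
    result = EvalResult()
    splits = stratified_holdout(dataset, k=k, seed=train_config.seed)
    for fold, split in enumerate(splits):
        train = dataset.subset(split.train_ids)
        test = dataset.subset(split.test_ids)
        model = build_classifier(model_config, seed=train_config.seed + fold)
        train_classifier(model, train, train_config)
        truth = test.labels()
        x = patches_to_array(test.patches, model.config.input_size)
        streams = np.random.SeedSequence(train_config.seed + fold).spawn(len(test))
        rngs = [np.random.default_rng(s) for s in streams]
        scores = model.mc_posterior_batch(x, T, rngs).mean(axis=1)
        preds = scores.argmax(axis=1)
        result.fold_accuracies.append(1.0 - error_rate(preds, truth))
        _, roc_aucs, mean_roc = roc_auc_one_vs_all(scores, truth)
        _, pr_aucs, mean_pr = precision_recall_one_vs_all(scores, truth)
        result.fold_roc_aucs.append(mean_roc)
        result.fold_pr_aucs.append(mean_pr)
        if fold == 0:
            result.per_class_roc_auc = roc_aucs
            result.per_class_pr_auc = pr_aucs
    return result
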