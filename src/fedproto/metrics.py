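"""Episode-level and aggregate evaluation.

Predictions from all test episodes are pooled into one confusion matrix
over the global class ids, from which accuracy and macro-averaged (i.e.
unweighted across classes) one-vs-rest precision, recall and F1 are
derived. Reported values follow the convention of three decimals for the
macro metrics and one decimal for accuracy in percent, rounded half away
from zero. For 2-way evaluation the probability assigned to the larger
global class id doubles as a score for ROC-AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exam_io import DatasetIndex
from .fewshot import EmbeddingNetwork, classify_queries, compute_prototypes, sample_episode
from .training import Checkpoint, EpisodeSpec, VolumePipeline, restore_backbone
from .preprocess import AugmentConfig

logger = logging.getLogger("fedproto")


class UndefinedAUCError(ValueError):
    """AUC requires both classes to be present."""


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    labels: List[int]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP
    ))


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame
    n_tasks: int = 0
    auc: Optional[float] = None

    def __post_init__(self):
        for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def rounded(self) -> Dict[str, float]:
        """Reporting convention: accuracy as percent to 1 decimal, macro
        metrics to 3 decimals, half-way cases rounded away from zero."""
        out = {
            "accuracy_pct": _round_half_up(100.0 * self.accuracy, 1),
            "macro_precision": _round_half_up(self.macro_precision, 3),
            "macro_recall": _round_half_up(self.macro_recall, 3),
            "macro_f1": _round_half_up(self.macro_f1, 3),
        }
        if self.auc is not None:
            out["auc"] = _round_half_up(self.auc, 2)
        return out

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "auc": self.auc,
            "n_tasks": self.n_tasks,
            "rounded": self.rounded(),
            "per_class": self.per_class.to_dict(orient="index"),
        }


def confusion_from_predictions(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    labels: Sequence[int],
) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted labels must have equal length")
    labels = list(labels)
    pos = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels.tolist(), predicted_labels.tolist()):
        if t not in pos or p not in pos:
            raise ValueError(f"label outside declared set: true={t}, predicted={p}")
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(labels, counts)


def macro_metrics_from_counts(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus macro one-vs-rest precision/recall/F1 from counts."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    if (tp + fp == 0).any():
        logger.warning(
            "classes %s were never predicted; their precision is defined as 0",
            [cm.labels[i] for i in np.flatnonzero(tp + fp == 0)],
        )
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "support": counts.sum(axis=1)},
        index=cm.labels,
    )
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        per_class=per_class,
    )


def roc_auc(scores: Sequence[float], true_binary_labels: Sequence[int]) -> float:
    """Rank-based (midrank-tied) AUC of positive-class scores."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(true_binary_labels)
    if len(set(labels.tolist())) < 2:
        raise UndefinedAUCError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_model(
    checkpoint: Checkpoint,
    test_index: DatasetIndex,
    n_tasks: int = 100,
    spec: EpisodeSpec = EpisodeSpec(2, 8),
    n_query: int = 10,
    rng: Optional[np.random.Generator] = None,
    augment: Optional[AugmentConfig] = None,
    plane: str = "axial",
    target_depth: int = 15,
    pipeline: Optional[VolumePipeline] = None,
    backbone: Optional[EmbeddingNetwork] = None,
) -> Tuple[MetricsReport, ConfusionMatrix]:
    """Episodic test protocol: sample ``n_tasks`` episodes, classify all
    queries, pool predictions (mapped back to global class ids) into one
    confusion matrix, and derive the metric report.

    For 2-way episodes the softmax probability of the larger global class
    id is collected per query and an AUC is attached when both classes
    appear among the pooled queries.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if backbone is None:
        backbone = restore_backbone(checkpoint)
    if pipeline is None:
        pipeline = VolumePipeline(plane, augment or AugmentConfig(), target_depth)
    spec = EpisodeSpec(*spec)
    all_true: List[int] = []
    all_pred: List[int] = []
    scores: List[float] = []
    score_labels: List[int] = []
    for _ in range(n_tasks):
        episode = sample_episode(test_index, spec.n_way, spec.k_shot, n_query, rng)
        items = list(episode.support_items) + list(episode.query_items)
        x = pipeline.batch(items, None, train_mode=False)
        z = backbone.embed(x, train=False)
        n_support = len(episode.support_items)
        protos = compute_prototypes(z[:n_support], episode.support_labels)
        _, preds, probs = classify_queries(protos, z[n_support:])
        global_ids = episode.class_map
        all_true.extend(global_ids[t] for t in episode.query_labels.tolist())
        all_pred.extend(global_ids[p] for p in preds.tolist())
        if spec.n_way == 2:
            # positive class = larger global class id
            pos_col = int(np.argmax(global_ids))
            scores.extend(probs[:, pos_col].tolist())
            score_labels.extend(
                int(global_ids[t] == max(global_ids))
                for t in episode.query_labels.tolist()
            )
    labels = sorted(test_index.class_counts)
    cm = confusion_from_predictions(all_true, all_pred, labels)
    report = macro_metrics_from_counts(cm)
    report.n_tasks = n_tasks
    if spec.n_way == 2 and len(set(score_labels)) == 2:
        report.auc = roc_auc(scores, score_labels)
    return report, cm
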