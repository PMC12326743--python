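"""Centralized episodic training and disjoint-class fine-tuning.

Training runs a fixed number of episodes ("tasks") per epoch: each task is
an n-way k-shot problem (3-way 5-shot by default); the query cross-entropy
of the prototypical classifier is backpropagated through the embedding
network and one SGD step (momentum 0.9, weight decay 5e-4) is taken per
task. The learning rate starts at 0.01 and is multiplied by gamma = 0.1 at
task milestones 120 and 160, counted globally across epochs. After each
epoch a validation pass (2-way 8-shot by default, 100 tasks) scores query
accuracy without gradient updates; the checkpoint with the highest
validation accuracy — including the untrained initialization — is kept.

Fine-tuning reruns the same loop from a trained checkpoint on classes
disjoint from the original training classes (3-way 5-shot training, 2-way
5-shot validation); when fewer classes are available than the configured
n_way, the episode width is clamped down and the clamp is logged.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from ._nn import SGD, ModelWeights, load_weights, save_weights
from .exam_io import DatasetIndex, ExamRecord
from .fewshot import (
    EmbeddingNetwork,
    Episode,
    compute_prototypes,
    classify_queries,
    episode_loss,
    episode_loss_grad,
    sample_episode,
)
from .preprocess import AugmentConfig, preprocess_volume, standardize_slices, augment_volume

logger = logging.getLogger("fedproto")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class ProtocolError(ValueError):
    """Fine-tuning classes overlap the training-stage classes."""


class EpisodeSpec(NamedTuple):
    n_way: int
    k_shot: int


@dataclass
class TrainConfig:
    """Optimizer schedule and episode geometry for one training stage."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    milestones: Tuple[int, ...] = (120, 160)
    gamma: float = 0.1
    tasks_per_epoch_train: int = 500
    tasks_per_epoch_val: int = 100
    epochs: int = 10
    train_spec: EpisodeSpec = EpisodeSpec(3, 5)
    val_spec: EpisodeSpec = EpisodeSpec(2, 8)
    n_query: int = 10
    val_n_query: int = 10
    seed: int = 0
    plane: str = "axial"
    target_depth: int = 15
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    milestones_per_epoch: bool = False  # False: global task counter (literal reading)

    def __post_init__(self):
        if isinstance(self.train_spec, (tuple, list)) and not isinstance(self.train_spec, EpisodeSpec):
            self.train_spec = EpisodeSpec(*self.train_spec)
        if isinstance(self.val_spec, (tuple, list)) and not isinstance(self.val_spec, EpisodeSpec):
            self.val_spec = EpisodeSpec(*self.val_spec)
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")


FINETUNE_VAL_SPEC = EpisodeSpec(2, 5)


def finetune_config(cfg: TrainConfig, **overrides) -> TrainConfig:
    """The fine-tuning stage reuses the optimizer but validates 2-way 5-shot."""
    return replace(cfg, val_spec=FINETUNE_VAL_SPEC, **overrides)


@dataclass
class Checkpoint:
    weights: ModelWeights
    val_accuracy: float
    epoch: int
    task_counter: int
    classes: List[int] = field(default_factory=list)
    backbone: str = "tiny3d"
    embed_dim: int = 64

    def __post_init__(self):
        if not 0.0 <= self.val_accuracy <= 1.0:
            raise ValueError("val_accuracy must lie in [0, 1]")


def lr_at_task(cfg: TrainConfig, task_counter: int) -> float:
    """MultiStep schedule: lr * gamma^(number of milestones <= task_counter)."""
    if task_counter < 0:
        raise ValueError("task_counter must be non-negative")
    n_passed = bisect.bisect_right(list(cfg.milestones), task_counter)
    return cfg.lr * cfg.gamma**n_passed


class VolumePipeline:
    """Per-exam preprocessing cache plus per-episode augmentation.

    The standardized, min-max-normalized single-channel volume is cached per
    exam; augmentation (train mode) or plain resize (eval) is applied per
    episode and the channel is replicated to 3 afterwards, which is
    equivalent to augmenting the replicated volume since all channels are
    identical and the transform is channel-wise.
    """

    def __init__(self, plane: str, augment: AugmentConfig, target_depth: int = 15):
        self.plane = plane
        self.augment = augment
        self.target_depth = target_depth
        self._cache: Dict[str, np.ndarray] = {}

    def base(self, record: ExamRecord) -> np.ndarray:
        cached = self._cache.get(record.exam_id)
        if cached is None:
            std = standardize_slices(record.volume(self.plane), self.target_depth)
            cached = preprocess_volume(std)[0]  # channels identical: keep one
            self._cache[record.exam_id] = cached
        return cached

    def batch(
        self,
        records: Sequence[ExamRecord],
        rng: Optional[np.random.Generator],
        train_mode: bool,
    ) -> np.ndarray:
        vols = [
            augment_volume(self.base(r), self.augment, rng, train_mode=train_mode)
            for r in records
        ]
        stack = np.stack(vols).astype(np.float32)[:, None]
        return np.repeat(stack, 3, axis=1)


def run_episode_forward(
    backbone: EmbeddingNetwork,
    episode: Episode,
    pipeline: VolumePipeline,
    rng: Optional[np.random.Generator],
    train_mode: bool,
):
    """Embed an episode and classify its queries.

    Returns (loss, accuracy, logits, predictions, embeddings) with the
    support embeddings first in the embedding matrix.
    """
    items = list(episode.support_items) + list(episode.query_items)
    x = pipeline.batch(items, rng, train_mode=train_mode)
    z = backbone.embed(x, train=train_mode)
    n_support = len(episode.support_items)
    protos = compute_prototypes(z[:n_support], episode.support_labels)
    logits, preds, _ = classify_queries(protos, z[n_support:])
    loss = episode_loss(logits, episode.query_labels)
    accuracy = float(np.mean(preds == episode.query_labels))
    return loss, accuracy, logits, preds, z


def _episode_backward(
    backbone: EmbeddingNetwork,
    episode: Episode,
    z: np.ndarray,
    logits: np.ndarray,
) -> None:
    """Backpropagate d(cross-entropy)/d(embeddings) into the backbone."""
    n_support = len(episode.support_items)
    zs = np.asarray(z[:n_support], dtype=np.float64)
    zq = np.asarray(z[n_support:], dtype=np.float64)
    labels = episode.support_labels
    classes = sorted(set(labels.tolist()))
    protos = np.stack([zs[labels == k].mean(axis=0) for k in classes])
    g = episode_loss_grad(logits, episode.query_labels)  # (Q, K)
    # logits[q, k] = -||zq_q - c_k||^2
    dzq = -2.0 * (zq * g.sum(axis=1, keepdims=True) - g @ protos)
    dprotos = 2.0 * (g.T @ zq - g.sum(axis=0)[:, None] * protos)
    dzs = np.zeros_like(zs)
    for i, k in enumerate(classes):
        members = labels == k
        dzs[members] = dprotos[i] / members.sum()
    backbone.backward(np.vstack([dzs, dzq]).astype(np.float32))


def evaluate_accuracy(
    backbone: EmbeddingNetwork,
    index: DatasetIndex,
    spec: EpisodeSpec,
    n_tasks: int,
    n_query: int,
    pipeline: VolumePipeline,
    rng: np.random.Generator,
) -> float:
    """Mean per-episode query accuracy over ``n_tasks`` evaluation episodes."""
    accs = []
    for _ in range(n_tasks):
        episode = sample_episode(index, spec.n_way, spec.k_shot, n_query, rng)
        _, acc, _, _, _ = run_episode_forward(backbone, episode, pipeline, None, train_mode=False)
        accs.append(acc)
    return float(np.mean(accs))


def train_centralized(
    backbone: EmbeddingNetwork,
    train_index: DatasetIndex,
    val_index: DatasetIndex,
    cfg: TrainConfig,
) -> Tuple[Checkpoint, List[dict]]:
    """Episodic training loop with best-validation checkpoint selection."""
    pipeline = VolumePipeline(cfg.plane, cfg.augment, cfg.target_depth)
    optimizer = SGD(backbone.net, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    sample_rng = np.random.default_rng([cfg.seed % 2**31, 11])
    aug_rng = np.random.default_rng([cfg.seed % 2**31, 13])
    val_rng_for = lambda epoch: np.random.default_rng([cfg.seed % 2**31, 17, epoch])

    n_way = min(cfg.train_spec.n_way, len(train_index.class_counts))
    if n_way < cfg.train_spec.n_way:
        logger.info(
            "clamping training episodes from %d-way to %d-way (only %d classes)",
            cfg.train_spec.n_way, n_way, n_way,
        )
    val_n_way = min(cfg.val_spec.n_way, len(val_index.class_counts))

    best = Checkpoint(
        weights=backbone.weights,
        val_accuracy=evaluate_accuracy(
            backbone, val_index, EpisodeSpec(val_n_way, cfg.val_spec.k_shot),
            cfg.tasks_per_epoch_val, cfg.val_n_query, pipeline, val_rng_for(0),
        ),
        epoch=0,
        task_counter=0,
        classes=train_index.classes(),
        backbone=backbone.name,
        embed_dim=backbone.embed_dim,
    )
    history: List[dict] = [
        {"epoch": 0, "mean_train_loss": None, "val_accuracy": best.val_accuracy}
    ]
    task_counter = 0
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for _ in range(cfg.tasks_per_epoch_train):
            if cfg.milestones_per_epoch:
                lr = lr_at_task(cfg, task_counter % cfg.tasks_per_epoch_train)
            else:
                lr = lr_at_task(cfg, task_counter)
            episode = sample_episode(
                train_index, n_way, cfg.train_spec.k_shot, cfg.n_query, sample_rng
            )
            loss, _, logits, _, z = run_episode_forward(
                backbone, episode, pipeline, aug_rng, train_mode=True
            )
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at task {task_counter}")
            backbone.net.zero_grad()
            _episode_backward(backbone, episode, z, logits)
            optimizer.step(lr)
            losses.append(loss)
            task_counter += 1
        val_acc = evaluate_accuracy(
            backbone, val_index, EpisodeSpec(val_n_way, cfg.val_spec.k_shot),
            cfg.tasks_per_epoch_val, cfg.val_n_query, pipeline, val_rng_for(epoch),
        )
        history.append(
            {"epoch": epoch, "mean_train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
        logger.info("epoch %d: train loss %.4f, val accuracy %.4f",
                    epoch, history[-1]["mean_train_loss"], val_acc)
        if val_acc > best.val_accuracy:
            best = Checkpoint(
                weights=backbone.weights,
                val_accuracy=val_acc,
                epoch=epoch,
                task_counter=task_counter,
                classes=train_index.classes(),
                backbone=backbone.name,
                embed_dim=backbone.embed_dim,
            )
    return best, history


def finetune(
    start: Checkpoint,
    finetune_index: DatasetIndex,
    val_index: DatasetIndex,
    cfg: TrainConfig,
    allow_overlap: bool = False,
) -> Tuple[Checkpoint, List[dict]]:
    """Continue episodic training from ``start`` on disjoint classes."""
    overlap = set(start.classes) & set(finetune_index.class_counts)
    if overlap and not allow_overlap:
        raise ProtocolError(
            f"fine-tuning classes {sorted(overlap)} overlap the training stage"
        )
    if cfg.epochs == 0:
        return start, []
    from .fewshot import build_backbone

    backbone = build_backbone(start.backbone, start.embed_dim, seed=cfg.seed,
                              init_weights=start.weights)
    ckpt, history = train_centralized(backbone, finetune_index, val_index, cfg)
    ckpt.classes = finetune_index.classes()
    return ckpt, history


def restore_backbone(ckpt: Checkpoint, seed: int = 0) -> EmbeddingNetwork:
    from .fewshot import build_backbone

    return build_backbone(ckpt.backbone, ckpt.embed_dim, seed=seed, init_weights=ckpt.weights)


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Weight archive (.npz) plus JSON sidecar with metadata."""
    path = Path(path)
    save_weights(ckpt.weights, path.with_suffix(".npz"))
    sidecar = {
        "val_accuracy": ckpt.val_accuracy,
        "epoch": ckpt.epoch,
        "task_counter": ckpt.task_counter,
        "classes": list(map(int, ckpt.classes)),
        "backbone": ckpt.backbone,
        "embed_dim": ckpt.embed_dim,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Checkpoint(weights=load_weights(path.with_suffix(".npz")), **meta)


def write_history(history: List[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)
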