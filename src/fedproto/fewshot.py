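"""Episodic n-way k-shot sampling and prototypical classification.

An episode is one self-contained few-shot task: ``n_way`` classes, each
contributing ``k_shot`` labeled support exams and ``n_query`` query exams.
Class prototypes are the arithmetic means of the support embeddings,

    c_k = (1 / |S_k|) * sum_{(x_i, y_i) in S_k} f_phi(x_i),

and a query is assigned to the nearest prototype under squared Euclidean
distance; the negative squared distances act as logits for a softmax, whose
cross-entropy against the query labels is the training loss.

The embedding backbone f_phi is pluggable: a small three-block 3-D CNN
(``tiny3d``) suited to desk-scale experiments, or 3-D ResNet variants of
depth 10/18/34/50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import ModelWeights
from .exam_io import DatasetIndex, ExamRecord


class SamplingError(ValueError):
    """Dataset cannot furnish the requested episode geometry."""


# ---------------------------------------------------------------------------
# Embedding backbones
# ---------------------------------------------------------------------------

BACKBONE_NAMES = ("tiny3d", "resnet3d-10", "resnet3d-18", "resnet3d-34", "resnet3d-50")

_RESNET_SPECS = {
    # name -> (block kind, blocks per stage)
    "resnet3d-10": ("basic", (1, 1, 1, 1)),
    "resnet3d-18": ("basic", (2, 2, 2, 2)),
    "resnet3d-34": ("basic", (3, 4, 6, 3)),
    "resnet3d-50": ("bottleneck", (3, 4, 6, 3)),
}


@dataclass
class EmbeddingNetwork:
    """A named backbone mapping (N, 3, D, H, W) batches to (N, embed_dim)."""

    name: str
    embed_dim: int
    net: _nn.Layer

    def embed(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_nn.DTYPE)
        if x.ndim != 5 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, D, H, W) input, got {x.shape}")
        return self.net.forward(x, train=train)

    def backward(self, d_embeddings: np.ndarray) -> None:
        self.net.backward(np.ascontiguousarray(d_embeddings, dtype=_nn.DTYPE))

    @property
    def weights(self) -> ModelWeights:
        return self.net.state_dict()

    def load_weights(self, weights: ModelWeights) -> None:
        self.net.load_state_dict(weights)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.net.parameters().values())


def _tiny3d(embed_dim: int, rng: np.random.Generator) -> _nn.Layer:
    """Three conv-pool blocks + global average pool + linear head.

    The first convolution downsamples in-plane (stride 1x2x2) so the
    dominant GEMM runs at quarter resolution."""
    return _nn.Sequential(
        conv1=_nn.Conv3d(3, 8, 3, stride=(1, 2, 2), pad=1, rng=rng),
        relu1=_nn.ReLU(),
        pool1=_nn.MaxPool3d(),
        conv2=_nn.Conv3d(8, 16, 3, pad=1, rng=rng),
        relu2=_nn.ReLU(),
        pool2=_nn.MaxPool3d(),
        conv3=_nn.Conv3d(16, 32, 3, pad=1, rng=rng),
        relu3=_nn.ReLU(),
        pool3=_nn.MaxPool3d(),
        gap=_nn.GlobalAvgPool3d(),
        fc=_nn.Linear(32, embed_dim, rng=rng),
    )


def _basic_block(c_in, c_out, stride, rng) -> _nn.ResidualBlock:
    branch = _nn.Sequential(
        conv1=_nn.Conv3d(c_in, c_out, 3, stride=stride, pad=1, bias=False, rng=rng),
        bn1=_nn.BatchNorm3d(c_out),
        relu=_nn.ReLU(),
        conv2=_nn.Conv3d(c_out, c_out, 3, pad=1, bias=False, rng=rng),
        bn2=_nn.BatchNorm3d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = _nn.Sequential(
            conv=_nn.Conv3d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
            bn=_nn.BatchNorm3d(c_out),
        )
    return _nn.ResidualBlock(branch, shortcut)


def _bottleneck_block(c_in, c_mid, stride, rng) -> _nn.ResidualBlock:
    c_out = c_mid * 4
    branch = _nn.Sequential(
        conv1=_nn.Conv3d(c_in, c_mid, 1, bias=False, rng=rng),
        bn1=_nn.BatchNorm3d(c_mid),
        relu1=_nn.ReLU(),
        conv2=_nn.Conv3d(c_mid, c_mid, 3, stride=stride, pad=1, bias=False, rng=rng),
        bn2=_nn.BatchNorm3d(c_mid),
        relu2=_nn.ReLU(),
        conv3=_nn.Conv3d(c_mid, c_out, 1, bias=False, rng=rng),
        bn3=_nn.BatchNorm3d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = _nn.Sequential(
            conv=_nn.Conv3d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
            bn=_nn.BatchNorm3d(c_out),
        )
    return _nn.ResidualBlock(branch, shortcut)


def _resnet3d(kind: str, blocks: Sequence[int], embed_dim: int,
              rng: np.random.Generator) -> _nn.Layer:
    widths = (64, 128, 256, 512)
    expansion = 4 if kind == "bottleneck" else 1
    layers: Dict[str, _nn.Layer] = {
        "stem_conv": _nn.Conv3d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        "stem_bn": _nn.BatchNorm3d(64),
        "stem_relu": _nn.ReLU(),
        "stem_pool": _nn.MaxPool3d(),
    }
    c_in = 64
    for stage, (width, n_blocks) in enumerate(zip(widths, blocks), start=1):
        stage_blocks = []
        for b in range(n_blocks):
            stride = 2 if (b == 0 and stage > 1) else 1
            if kind == "basic":
                stage_blocks.append(_basic_block(c_in, width, stride, rng))
                c_in = width
            else:
                stage_blocks.append(_bottleneck_block(c_in, width, stride, rng))
                c_in = width * expansion
        layers[f"layer{stage}"] = _nn.Sequential(
            **{str(i): blk for i, blk in enumerate(stage_blocks)}
        )
    layers["gap"] = _nn.GlobalAvgPool3d()
    layers["fc"] = _nn.Linear(c_in, embed_dim, rng=rng)
    return _nn.Sequential(**layers)


def build_backbone(
    name: str = "tiny3d",
    embed_dim: int = 64,
    seed: int = 0,
    init_weights: Optional[ModelWeights] = None,
) -> EmbeddingNetwork:
    """Construct a deterministically initialized embedding network.

    ``init_weights`` (an ordered name -> array mapping, e.g. loaded from an
    ``.npz`` archive) overrides the seeded initialization; names and shapes
    must match exactly.
    """
    if name not in BACKBONE_NAMES:
        raise ValueError(f"unknown backbone {name!r}; choose from {BACKBONE_NAMES}")
    rng = np.random.default_rng(seed)
    if name == "tiny3d":
        net = _tiny3d(embed_dim, rng)
    else:
        kind, blocks = _RESNET_SPECS[name]
        net = _resnet3d(kind, blocks, embed_dim, rng)
    backbone = EmbeddingNetwork(name, embed_dim, net)
    if init_weights is not None:
        backbone.load_weights(init_weights)
    return backbone


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------

@dataclass
class Episode:
    """One n-way k-shot task with support/query exams and episode labels.

    Episode labels run 0..n_way-1; ``class_map`` records the global class id
    behind each episode label (ascending global order).
    """

    support_items: List[ExamRecord]
    support_labels: np.ndarray
    query_items: List[ExamRecord]
    query_labels: np.ndarray
    n_way: int
    k_shot: int
    n_query_per_class: int
    class_map: List[int] = field(default_factory=list)

    def __post_init__(self):
        self.support_labels = np.asarray(self.support_labels, dtype=np.int64)
        self.query_labels = np.asarray(self.query_labels, dtype=np.int64)
        if len(self.support_items) != self.n_way * self.k_shot:
            raise ValueError("support size must be n_way * k_shot")
        support_ids = {r.exam_id for r in self.support_items}
        query_ids = {r.exam_id for r in self.query_items}
        if support_ids & query_ids:
            raise ValueError("support and query sets must be disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_way": self.n_way,
                "k_shot": self.k_shot,
                "n_query_per_class": self.n_query_per_class,
                "class_map": list(map(int, self.class_map)),
                "support": [
                    {"exam_id": r.exam_id, "label": int(l)}
                    for r, l in zip(self.support_items, self.support_labels)
                ],
                "query": [
                    {"exam_id": r.exam_id, "label": int(l)}
                    for r, l in zip(self.query_items, self.query_labels)
                ],
            },
            indent=2,
        )


def sample_episode(
    index: DatasetIndex,
    n_way: int,
    k_shot: int,
    n_query: int,
    rng: np.random.Generator,
) -> Episode:
    """Draw one episode: classes without replacement, then disjoint
    support/query exams without replacement within each class."""
    pools = index.by_class()
    if len(pools) < n_way:
        raise SamplingError(
            f"need {n_way} classes but index has only {len(pools)}: {sorted(pools)}"
        )
    need = k_shot + n_query
    eligible = sorted(c for c, recs in pools.items() if len(recs) >= need)
    short = sorted(set(pools) - set(eligible))
    if len(eligible) < n_way:
        raise SamplingError(
            f"classes {short} have fewer than k_shot + n_query = {need} exams"
        )
    chosen = sorted(rng.choice(eligible, size=n_way, replace=False).tolist())
    support_items, support_labels, query_items, query_labels = [], [], [], []
    for episode_label, global_id in enumerate(chosen):
        recs = pools[global_id]
        picks = rng.choice(len(recs), size=need, replace=False)
        for i in picks[:k_shot]:
            support_items.append(recs[i])
            support_labels.append(episode_label)
        for i in picks[k_shot:]:
            query_items.append(recs[i])
            query_labels.append(episode_label)
    return Episode(
        support_items, np.array(support_labels), query_items, np.array(query_labels),
        n_way=n_way, k_shot=k_shot, n_query_per_class=n_query, class_map=chosen,
    )


# ---------------------------------------------------------------------------
# Prototypes and classification
# ---------------------------------------------------------------------------

@dataclass
class PrototypeSet:
    class_order: List[int]
    vectors: np.ndarray  # (n_classes, embed_dim)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("prototypes must be finite")
        if len(self.class_order) != self.vectors.shape[0]:
            raise ValueError("one vector per class required")


def compute_prototypes(
    support_embeddings: np.ndarray,
    support_labels: Sequence[int],
) -> PrototypeSet:
    """Per-class arithmetic mean of support embeddings, ascending class order."""
    emb = np.asarray(support_embeddings, dtype=np.float64)
    labels = np.asarray(support_labels)
    classes = sorted(set(labels.tolist()))
    vectors = np.stack([emb[labels == k].mean(axis=0) for k in classes])
    return PrototypeSet(classes, vectors)


def classify_queries(
    protos: PrototypeSet,
    query_embeddings: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-prototype classification under squared Euclidean distance.

    Returns (logits, predictions, probabilities) where
    ``logits[q, k] = -||z_q - c_k||^2`` and probabilities are the softmax of
    the logits. Distance ties resolve to the lowest class position.
    """
    q = np.asarray(query_embeddings, dtype=np.float64)
    if q.ndim != 2 or q.shape[1] != protos.vectors.shape[1]:
        raise ValueError(
            f"query embedding dim {q.shape} does not match prototypes "
            f"{protos.vectors.shape}"
        )
    diff = q[:, None, :] - protos.vectors[None, :, :]
    logits = -np.sum(diff * diff, axis=2)
    predictions = logits.argmax(axis=1)  # argmax takes the first maximum: low-id tie-break
    probabilities = softmax(logits)
    return logits, predictions, probabilities


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def episode_loss(logits: np.ndarray, query_labels: Sequence[int]) -> float:
    """Mean cross-entropy of softmax(logits) against the query labels."""
    labels = np.asarray(query_labels)
    n, k = np.asarray(logits).shape
    if labels.shape != (n,):
        raise ValueError("one label per query required")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValueError(f"labels must lie in 0..{k - 1}")
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(n), labels].mean())


def episode_loss_grad(logits: np.ndarray, query_labels: Sequence[int]) -> np.ndarray:
    """d(mean cross-entropy)/d(logits) = (softmax - onehot) / n_query."""
    labels = np.asarray(query_labels)
    p = softmax(np.asarray(logits, dtype=np.float64))
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)
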