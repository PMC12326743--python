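"""Two-stage horizontal federated simulation.

Clients hold disjoint, class-stratified shards of the training data and are
simulated in-process, one after another, each with its own derived seed.
One round runs: local episodic training on each shard; upload of each
client's best-validation weights; size-weighted federated averaging
(FedAvg, W = sum_i n_i W_i / sum_i n_i); redistribution of the averaged
weights; and local fine-tuning on the (also sharded) disjoint fine-tuning
classes. The evaluated global model is either a second aggregation of the
fine-tuned weights (default) or the fine-tuned client model with the best
validation accuracy.

Raw exam volumes never cross the client boundary: the client API exposes
only weight mappings and scalar metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._nn import ModelWeights
from .exam_io import DatasetIndex
from .fewshot import build_backbone
from .training import Checkpoint, TrainConfig, finetune, finetune_config, train_centralized


class StratificationError(ValueError):
    """A class has fewer exams than there are clients."""


class AggregationError(ValueError):
    """Client weight archives disagree in names or shapes."""


@dataclass
class FedConfig:
    n_clients: int = 2
    rounds: int = 1
    partition_seed: int = 0
    aggregate_after_finetune: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)
    #: stage-2 budget; derived from ``train`` (2-way 5-shot validation) when unset
    finetune_train: Optional[TrainConfig] = None

    def __post_init__(self):
        if self.n_clients < 2:
            raise ValueError("n_clients must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def partition_clients(
    index: DatasetIndex,
    n_clients: int,
    rng: np.random.Generator,
) -> List[DatasetIndex]:
    """Disjoint, exhaustive, class-stratified partition of an index.

    Within each class the exams are shuffled and dealt out evenly; the
    remainder is assigned round-robin starting from a random client.
    """
    if len(index) == 0:
        raise ValueError("cannot partition an empty index")
    shards: List[list] = [[] for _ in range(n_clients)]
    for class_id in sorted(index.class_counts):
        recs = [r for r in index.records if r.class_id == class_id]
        if len(recs) < n_clients:
            raise StratificationError(
                f"class {class_id} has {len(recs)} exams but {n_clients} clients"
            )
        order = rng.permutation(len(recs))
        start = int(rng.integers(n_clients))
        for pos, i in enumerate(order):
            shards[(start + pos) % n_clients].append(recs[i])
    return [DatasetIndex(s, split=index.split) for s in shards]


def fedavg(
    client_weights: Sequence[ModelWeights],
    client_sizes: Sequence[int],
) -> ModelWeights:
    """Size-weighted parameter average, W = sum n_i W_i / sum n_i."""
    if not client_weights:
        raise AggregationError("no client weights to aggregate")
    if len(client_weights) != len(client_sizes):
        raise AggregationError("one size per client required")
    if any(s <= 0 for s in client_sizes):
        raise AggregationError("client sizes must be positive")
    names = list(client_weights[0])
    for w in client_weights[1:]:
        if list(w) != names:
            raise AggregationError("client weight archives have different parameter names")
    total = float(sum(client_sizes))
    out: ModelWeights = {}
    for name in names:
        ref_shape = np.asarray(client_weights[0][name]).shape
        acc = np.zeros(ref_shape, dtype=np.float64)
        for w, s in zip(client_weights, client_sizes):
            arr = np.asarray(w[name])
            if arr.shape != ref_shape:
                raise AggregationError(
                    f"shape mismatch for {name!r}: {arr.shape} vs {ref_shape}"
                )
            acc += (s / total) * arr
        out[name] = acc.astype(np.asarray(client_weights[0][name]).dtype)
    return out


class _ClientSim:
    """One simulated client; its data shards stay private to the instance.

    The public surface returns only weight mappings and scalar metrics —
    the simulation analogue of the privacy boundary.
    """

    def __init__(
        self,
        client_id: int,
        train_shard: DatasetIndex,
        finetune_shard: DatasetIndex,
        val_index: DatasetIndex,
        cfg: TrainConfig,
        ft_cfg: TrainConfig,
        backbone_name: str,
        embed_dim: int,
    ):
        self.client_id = client_id
        self.backbone_name = backbone_name
        self.embed_dim = embed_dim
        self.__train_shard = train_shard
        self.__finetune_shard = finetune_shard
        self.__val_index = val_index
        derived_seed = lambda c: (c.seed * 1000003 + 101 * client_id) % 2**31
        self.__cfg = replace(cfg, seed=derived_seed(cfg))
        self.__ft_cfg = replace(ft_cfg, seed=derived_seed(ft_cfg))
        self.n_train = len(train_shard)
        self.n_finetune = len(finetune_shard)
        self.history: List[dict] = []
        self.__checkpoint: Optional[Checkpoint] = None

    def train(self, init_weights: Optional[ModelWeights]) -> Tuple[ModelWeights, float]:
        cfg = self.__cfg
        backbone = build_backbone(
            self.backbone_name, self.embed_dim, seed=cfg.seed,
            init_weights=init_weights,
        )
        ckpt, hist = train_centralized(backbone, self.__train_shard, self.__val_index, cfg)
        self.__checkpoint = ckpt
        self.history.extend({"stage": "train", "client": self.client_id, **h} for h in hist)
        return ckpt.weights, ckpt.val_accuracy

    def finetune_local(self, global_weights: ModelWeights) -> Tuple[ModelWeights, float]:
        cfg = self.__ft_cfg
        start = replace(self.__checkpoint, weights=global_weights)
        ckpt, hist = finetune(start, self.__finetune_shard, self.__finetune_shard, cfg)
        self.__checkpoint = ckpt
        self.history.extend({"stage": "finetune", "client": self.client_id, **h} for h in hist)
        return ckpt.weights, ckpt.val_accuracy


@dataclass
class FederatedResult:
    global_checkpoint: Checkpoint
    client_histories: List[dict]
    final_model_rule: str  # "aggregate" or "best_client"
    client_val_accuracies: List[float]


def run_federated(
    train_index: DatasetIndex,
    val_index: DatasetIndex,
    finetune_index: DatasetIndex,
    cfg: FedConfig,
    backbone_name: str = "tiny3d",
    embed_dim: int = 64,
) -> FederatedResult:
    """Train -> upload best weights -> FedAvg -> redistribute -> local
    fine-tune (-> optional second FedAvg), repeated for ``rounds``."""
    part_rng = np.random.default_rng([cfg.partition_seed % 2**31, 23])
    train_shards = partition_clients(train_index, cfg.n_clients, part_rng)
    finetune_shards = partition_clients(finetune_index, cfg.n_clients, part_rng)

    inner = cfg.train
    ft_cfg = cfg.finetune_train if cfg.finetune_train is not None else finetune_config(inner)
    clients = [
        _ClientSim(i, train_shards[i], finetune_shards[i], val_index, inner, ft_cfg,
                   backbone_name, embed_dim)
        for i in range(cfg.n_clients)
    ]

    # All clients start from one server-side initialization, the standard
    # FedAvg convention (averaging independently initialized networks is
    # meaningless under permutation symmetry).
    global_weights: Optional[ModelWeights] = build_backbone(
        backbone_name, embed_dim, seed=inner.seed
    ).weights
    rule = "aggregate" if cfg.aggregate_after_finetune else "best_client"
    val_accs: List[float] = []
    for _ in range(cfg.rounds):
        uploads = [c.train(global_weights) for c in clients]
        global_weights = fedavg(
            [w for w, _ in uploads], [c.n_train for c in clients]
        )
        tuned = [c.finetune_local(global_weights) for c in clients]
        val_accs = [acc for _, acc in tuned]
        if cfg.aggregate_after_finetune:
            global_weights = fedavg(
                [w for w, _ in tuned], [c.n_finetune for c in clients]
            )
            global_val = float(
                np.average(val_accs, weights=[c.n_finetune for c in clients])
            )
        else:
            best = int(np.argmax(val_accs))
            global_weights = tuned[best][0]
            global_val = val_accs[best]

    ckpt = Checkpoint(
        weights=global_weights,
        val_accuracy=global_val,
        epoch=inner.epochs,
        task_counter=cfg.rounds * inner.epochs * inner.tasks_per_epoch_train,
        classes=finetune_index.classes(),
        backbone=backbone_name,
        embed_dim=embed_dim,
    )
    histories = [h for c in clients for h in c.history]
    return FederatedResult(ckpt, histories, rule, val_accs)
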