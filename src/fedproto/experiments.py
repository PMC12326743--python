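"""Desk-scale end-to-end experiments on synthetic data.

These runs exercise the full two-stage protocol — episodic training on one
class subset, fine-tuning and testing on a disjoint subset, centralized
versus two-client federated — at CPU-friendly problem sizes: 48x48 source
images resized to 32x32, a tiny3d backbone, 2 epochs of 50 training tasks,
and a signal-to-noise ratio of 5 in the generator. The class-split grammar
mirrors the real protocol: train on classes (1, 2, 4), fine-tune and test
on the held-out pair (0, 3); the deliberately overlapping pair (3, 4)
serves as the hard control for the hardness-ordering check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .exam_io import DatasetIndex
from .federated import FedConfig, run_federated
from .fewshot import build_backbone
from .metrics import evaluate_model
from .preprocess import AugmentConfig
from .synthetic import SynthConfig, generate_balanced_index
from .training import (
    Checkpoint,
    EpisodeSpec,
    TrainConfig,
    finetune,
    finetune_config,
    train_centralized,
)

TRAIN_CLASSES = (1, 2, 4)
TEST_CLASSES = (0, 3)
HARD_CLASSES = (3, 4)
OUT_SIZE = 32


def desk_synth_config(seed: int) -> SynthConfig:
    return SynthConfig(
        image_size=48,
        signal_strength=5.0,
        noise_sd=1.0,
        planes=("axial",),
        seed=seed % 2**31,
    )


def desk_train_config(seed: int) -> TrainConfig:
    return TrainConfig(
        epochs=2,
        tasks_per_epoch_train=50,
        tasks_per_epoch_val=10,
        train_spec=EpisodeSpec(3, 5),
        val_spec=EpisodeSpec(2, 8),
        n_query=5,
        val_n_query=5,
        seed=seed % 2**31,
        plane="axial",
        augment=AugmentConfig(out_size=OUT_SIZE),
    )


def desk_finetune_config(seed: int) -> TrainConfig:
    return finetune_config(
        desk_train_config(seed), epochs=1, tasks_per_epoch_train=25,
    )


@dataclass
class Pools:
    train: DatasetIndex
    val: DatasetIndex
    finetune: DatasetIndex
    test: DatasetIndex
    hard: DatasetIndex


def build_pools(seed: int) -> Pools:
    cfg = desk_synth_config(seed)
    return Pools(
        train=generate_balanced_index(TRAIN_CLASSES, 24, cfg, stream=1),
        val=generate_balanced_index(TRAIN_CLASSES, 16, cfg, stream=2),
        finetune=generate_balanced_index(TEST_CLASSES, 24, cfg, stream=3),
        test=generate_balanced_index(TEST_CLASSES, 20, cfg, stream=4),
        hard=generate_balanced_index(HARD_CLASSES, 20, cfg, stream=5),
    )


def _test_accuracy(ckpt: Checkpoint, index: DatasetIndex, seed: int, n_tasks: int = 40) -> float:
    report, _ = evaluate_model(
        ckpt,
        index,
        n_tasks=n_tasks,
        spec=EpisodeSpec(2, 8),
        n_query=8,
        rng=np.random.default_rng([seed % 2**31, 71]),
        augment=AugmentConfig(out_size=OUT_SIZE),
        plane="axial",
    )
    return report.accuracy


def run_centralized_experiment(seed: int, pools: Pools = None) -> Dict[str, float]:
    """Centralized two-stage run; returns test accuracies on the held-out
    pair (0, 3) and on the hard overlapping pair (3, 4)."""
    pools = pools or build_pools(seed)
    backbone = build_backbone("tiny3d", 64, seed=seed % 2**31)
    ckpt, _ = train_centralized(backbone, pools.train, pools.val, desk_train_config(seed))
    tuned, _ = finetune(ckpt, pools.finetune, pools.finetune, desk_finetune_config(seed))
    return {
        "centralized_accuracy": _test_accuracy(tuned, pools.test, seed),
        "hard_pair_accuracy": _test_accuracy(tuned, pools.hard, seed),
    }


def run_federated_experiment(seed: int, pools: Pools = None) -> Dict[str, float]:
    """Two-client, one-round federated run evaluated on the same test pool."""
    pools = pools or build_pools(seed)
    fed_cfg = FedConfig(
        n_clients=2,
        rounds=1,
        partition_seed=seed % 2**31,
        train=desk_train_config(seed),
        finetune_train=desk_finetune_config(seed),
    )
    result = run_federated(pools.train, pools.val, pools.finetune, fed_cfg)
    return {"federated_accuracy": _test_accuracy(result.global_checkpoint, pools.test, seed)}


def run_separability_experiment(seed: int) -> Dict[str, float]:
    """Full criterion experiment: centralized, federated, and hardness control."""
    pools = build_pools(seed)
    out = run_centralized_experiment(seed, pools)
    out.update(run_federated_experiment(seed, pools))
    out["centralized_minus_federated"] = (
        out["centralized_accuracy"] - out["federated_accuracy"]
    )
    return out
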