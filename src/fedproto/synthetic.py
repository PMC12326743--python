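"""Synthetic MRNet-layout data generator.

Emulates the structural features of a knee-MRI exam collection that the
pipeline depends on: per-exam variable-depth grayscale stacks (one per
acquisition plane), three two-column label tables, the five observed
label combinations, and an imbalanced class mixture (class 1 the most
frequent, class 3 the rarest).

Class-conditional signal is additive 3-D Gaussian blobs at fixed fractional
positions; which blobs are present, how large, and how bright is a
deterministic function of the class id. Classes 3 and 4 share their main
blob and differ only in the amplitude of the second — an amplitude contrast
that per-volume min-max normalization largely removes — making that pair
deliberately hard to separate while pairs involving class 0 (pure noise)
stay easy. This mirrors the qualitative hardness ordering of the class
splits in the real task. No anatomical realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Sequence, Tuple, Union

import numpy as np

from .exam_io import (
    DatasetIndex,
    ExamRecord,
    PLANES,
    decode_class,
    label_table_paths,
    load_dataset,
)

#: blob = (center fractions (d, h, w), sigma as fraction of image size,
#:         amplitude multiplier)
_Blob = Tuple[Tuple[float, float, float], float, float]

_CLASS_BLOBS: Dict[int, List[_Blob]] = {
    0: [],
    1: [((0.30, 0.30, 0.30), 0.10, 1.0)],
    2: [((0.70, 0.65, 0.60), 0.16, 1.0)],
    3: [((0.50, 0.50, 0.50), 0.12, 1.0), ((0.35, 0.70, 0.35), 0.10, 1.0)],
    # class 4 shares both blob sites with class 3; only the second blob's
    # amplitude differs, so the (3, 4) pair is the hard one by construction
    4: [((0.50, 0.50, 0.50), 0.12, 1.0), ((0.35, 0.70, 0.35), 0.10, 1.3)],
}


def class_blobs(class_id: int) -> List[_Blob]:
    """The deterministic blob signature of a class (test/analysis oracle)."""
    return list(_CLASS_BLOBS[int(class_id)])


@dataclass
class SynthConfig:
    n_exams: int = 200
    #: imbalanced mixture; class 1 largest, class 3 smallest
    class_proportions: Tuple[float, ...] = (0.20, 0.34, 0.18, 0.08, 0.20)
    depth_range: Tuple[int, int] = (17, 61)
    image_size: int = 64
    signal_strength: float = 5.0
    noise_sd: float = 1.0
    valid_fraction: float = 0.2
    planes: Tuple[str, ...] = PLANES
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be 5 non-negative values summing to 1")
        lo, hi = self.depth_range
        if not (2 <= lo <= hi <= 61):
            raise ValueError("depth_range must lie within [2, 61]")


def signal_field(class_id: int, shape: Tuple[int, int, int], cfg: SynthConfig) -> np.ndarray:
    """Noiseless additive class signal on a (D, H, W) grid."""
    d, h, w = shape
    out = np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(
        np.arange(d), np.arange(h), np.arange(w), indexing="ij"
    )
    for (fd, fh, fw), fsigma, amp in _CLASS_BLOBS[int(class_id)]:
        cd, ch, cw = fd * (d - 1), fh * (h - 1), fw * (w - 1)
        # anisotropic voxel grid: depth sigma scales with depth
        sd = max(fsigma * d, 1.0)
        sp = fsigma * max(h, w)
        r2 = ((zz - cd) / sd) ** 2 + ((yy - ch) / sp) ** 2 + ((xx - cw) / sp) ** 2
        out += (cfg.signal_strength * amp * np.exp(-0.5 * r2)).astype(np.float32)
    return out


def generate_exam(
    class_id: int,
    cfg: SynthConfig,
    rng: np.random.Generator,
    exam_id: str = "0000",
) -> ExamRecord:
    """One exam: three independent plane volumes of random depth with the
    class signal plus Gaussian noise; the label triple inverts the class id."""
    if not 0 <= int(class_id) <= 4:
        raise ValueError(f"class_id must be 0-4, got {class_id}")
    lo, hi = cfg.depth_range
    volumes: Dict[str, np.ndarray] = {}
    for plane in cfg.planes:
        depth = int(rng.integers(lo, hi + 1))
        shape = (depth, cfg.image_size, cfg.image_size)
        vol = rng.normal(0.0, cfg.noise_sd, size=shape).astype(np.float32)
        vol += signal_field(class_id, shape, cfg)
        volumes[plane] = vol
    triple = decode_class(class_id)
    return ExamRecord(exam_id, volumes, triple, int(class_id))


def draw_classes(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(5, size=n, p=np.asarray(cfg.class_proportions, dtype=float))


def generate_index(cfg: SynthConfig, split: str = "train") -> DatasetIndex:
    """In-memory dataset (no disk I/O) under the split's derived seed."""
    rng = np.random.default_rng([cfg.seed % 2**31, {"train": 1, "valid": 2}[split]])
    n = cfg.n_exams if split == "train" else max(1, round(cfg.n_exams * cfg.valid_fraction / (1 - cfg.valid_fraction)))
    classes = draw_classes(cfg, rng, n)
    records = [
        generate_exam(c, cfg, rng, exam_id=f"{i:04d}")
        for i, c in enumerate(classes)
    ]
    return DatasetIndex(records, split=split)


def generate_balanced_index(
    classes: Sequence[int],
    n_per_class: int,
    cfg: SynthConfig,
    split: str = "train",
    stream: int = 0,
) -> DatasetIndex:
    """Balanced in-memory pool over given classes (episodic experiments
    need every class to hold at least k_shot + n_query exams)."""
    rng = np.random.default_rng([cfg.seed % 2**31, 40 + stream])
    records = []
    i = 0
    for c in sorted(int(c) for c in classes):
        for _ in range(n_per_class):
            records.append(generate_exam(c, cfg, rng, exam_id=f"{stream}{i:04d}"))
            i += 1
    return DatasetIndex(records, split="train" if split not in ("train", "valid") else split)


class GeneratedDataset(NamedTuple):
    train: DatasetIndex
    valid: DatasetIndex


def generate_dataset(cfg: SynthConfig, root: Union[str, Path]) -> GeneratedDataset:
    """Write the full MRNet layout (volume files + label tables) for an
    80/20 train/valid split and return the re-loaded indices."""
    root = Path(root)
    rng = np.random.default_rng([cfg.seed % 2**31, 3])
    n_valid = int(round(cfg.n_exams * cfg.valid_fraction))
    n_train = cfg.n_exams - n_valid
    counter = 0
    for split, n in (("train", n_train), ("valid", n_valid)):
        for plane in cfg.planes:
            (root / split / plane).mkdir(parents=True, exist_ok=True)
        classes = draw_classes(cfg, rng, n)
        rows = {"abnormal": [], "acl": [], "meniscus": []}
        for c in classes:
            exam_id = f"{counter:04d}"
            counter += 1
            record = generate_exam(int(c), cfg, rng, exam_id=exam_id)
            for plane in cfg.planes:
                np.save(root / split / plane / f"{exam_id}.npy", record.volumes[plane])
            triple = record.triple
            rows["abnormal"].append((exam_id, triple.abnormal))
            rows["acl"].append((exam_id, triple.acl))
            rows["meniscus"].append((exam_id, triple.meniscus))
        for name, path in label_table_paths(root, split).items():
            path.write_text(
                "".join(f"{eid},{lab}\n" for eid, lab in rows[name])
            )
    return GeneratedDataset(
        train=load_dataset(root, "train", plane=cfg.planes),
        valid=load_dataset(root, "valid", plane=cfg.planes),
    )
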