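"""Volume preprocessing: slice-count standardization, normalization,
channel replication, and the training-time augmentation stack.

Raw exams have anywhere from 17 to 61 slices. They are resampled to a fixed
depth by placing output slices at uniformly spaced fractional positions
along the stack; an output that lands between two originals is a fixed
convex blend of 20% of the preceding and 80% of the subsequent slice, and
an output that lands exactly on an original copies it. Intensities are then
min-max scaled to [0, 1] per volume and the single grayscale channel is
replicated three times.

Augmentation (training only) draws one random transform per exam — resize,
50% horizontal and vertical flips, a rotation in [-45, 45] degrees, and a
random affine (scale/translate/rotate) — and applies it identically to
every slice so intra-volume anatomy stays coherent. Evaluation applies only
the resize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

DEFAULT_TARGET_DEPTH = 15
DEFAULT_OUT_SIZE = 224


class TooFewSlicesError(ValueError):
    """Volume has fewer than two slices."""


class DataError(ValueError):
    """Volume contains non-finite voxels."""


@dataclass
class AugmentConfig:
    """Training augmentation parameters (per-exam random draw)."""

    out_size: int = DEFAULT_OUT_SIZE
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rot_range: Tuple[float, float] = (-45.0, 45.0)
    affine_scale: Tuple[float, float] = (0.9, 1.1)
    affine_translate: Tuple[float, float] = (0.0, 0.1)
    affine_rot: Tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self):
        if self.out_size <= 0:
            raise ValueError("out_size must be positive")
        for p in (self.p_hflip, self.p_vflip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must be within [0, 1]")
        for lo, hi in (self.rot_range, self.affine_scale,
                       self.affine_translate, self.affine_rot):
            if lo > hi:
                raise ValueError("interval bounds must be ordered")


def standardize_slices(volume: np.ndarray, target_depth: int = DEFAULT_TARGET_DEPTH) -> np.ndarray:
    """Resample a (D, H, W) stack to ``target_depth`` slices.

    Output slice j sits at fractional position ``j * (D - 1) / (T - 1)``;
    integer positions copy the original slice, interior positions blend
    0.2 x preceding + 0.8 x subsequent. The first and last slices are
    always preserved verbatim.
    """
    volume = np.asarray(volume)
    if target_depth < 2:
        raise ValueError(f"target_depth must be >= 2, got {target_depth}")
    d = volume.shape[0]
    if d < 2:
        raise TooFewSlicesError(f"need at least 2 slices, got {d}")
    positions = np.arange(target_depth) * (d - 1) / (target_depth - 1)
    out = np.empty((target_depth,) + volume.shape[1:], dtype=np.result_type(volume, np.float32))
    for j, p in enumerate(positions):
        lo = int(np.floor(p))
        if abs(p - round(p)) < 1e-9:
            out[j] = volume[int(round(p))]
        else:
            out[j] = 0.2 * volume[lo] + 0.8 * volume[lo + 1]
    return out


def preprocess_volume(volume: np.ndarray) -> np.ndarray:
    """Min-max normalize a (D, H, W) stack to [0, 1] and replicate to 3 channels.

    Returns a (3, D, H, W) array; a constant volume maps to all zeros.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if not np.all(np.isfinite(volume)):
        raise DataError("volume contains non-finite voxels")
    lo, hi = float(volume.min()), float(volume.max())
    if hi > lo:
        scaled = (volume - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(volume)
    return np.repeat(scaled[None], 3, axis=0)


def _resize_slices(stack: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize of the trailing (H, W) dims of a (..., H, W) array."""
    h, w = stack.shape[-2:]
    if (h, w) == (out_size, out_size):
        return stack.astype(np.float32, copy=False)
    zoom = [1.0] * (stack.ndim - 2) + [out_size / h, out_size / w]
    return ndimage.zoom(stack, zoom, order=1, grid_mode=True, mode="nearest").astype(np.float32)


def _affine_matrix(angle_deg: float, scale: float, shift: Tuple[float, float],
                   size: int) -> Tuple[np.ndarray, np.ndarray]:
    """2-D rotation+scale about the slice center plus translation, as the
    (matrix, offset) pair consumed by ``scipy.ndimage.affine_transform``
    (output -> input mapping, hence the inversions)."""
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    m = np.linalg.inv(rot * scale)
    center = (size - 1) / 2.0
    c = np.array([center, center])
    offset = c - m @ (c + np.asarray(shift))
    return m, offset


def draw_augmentation(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """One per-exam random draw of all augmentation parameters."""
    return {
        "hflip": bool(rng.random() < cfg.p_hflip),
        "vflip": bool(rng.random() < cfg.p_vflip),
        "rotation": float(rng.uniform(*cfg.rot_range)),
        "affine_scale": float(rng.uniform(*cfg.affine_scale)),
        "affine_rot": float(rng.uniform(*cfg.affine_rot)),
        "affine_shift": tuple(
            float(v)
            for v in rng.uniform(cfg.affine_translate[0], cfg.affine_translate[1], size=2)
            * np.where(rng.random(2) < 0.5, -1.0, 1.0)
        ),
    }


def augment_volume(
    volume: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator = None,
    train_mode: bool = False,
) -> np.ndarray:
    """Resize every slice to ``out_size``; in training mode additionally
    apply one random flip/rotation/affine draw to all slices of the exam.

    Accepts (C, D, H, W) or (D, H, W); the channel axis is preserved.
    """
    volume = np.asarray(volume, dtype=np.float32)
    squeeze = volume.ndim == 3
    if squeeze:
        volume = volume[None]
    c, d = volume.shape[:2]
    out = _resize_slices(volume, cfg.out_size)
    if not train_mode:
        return out[0] if squeeze else out
    if rng is None:
        raise ValueError("training-mode augmentation requires an explicit rng")
    draw = draw_augmentation(cfg, rng)
    if draw["hflip"]:
        out = out[..., ::-1]
    if draw["vflip"]:
        out = out[..., ::-1, :]
    angle = draw["rotation"] + draw["affine_rot"]
    shift = np.array(draw["affine_shift"]) * cfg.out_size
    m, offset = _affine_matrix(angle, draw["affine_scale"], tuple(shift), cfg.out_size)
    flat = np.ascontiguousarray(out.reshape(c * d, cfg.out_size, cfg.out_size))
    warped = np.empty_like(flat)
    for i in range(flat.shape[0]):
        warped[i] = ndimage.affine_transform(
            flat[i], m, offset=offset, order=1, mode="constant", cval=0.0
        )
    result = warped.reshape(c, d, cfg.out_size, cfg.out_size)
    return result[0] if squeeze else result


def preprocess_exam(
    raw_volume: np.ndarray,
    target_depth: int = DEFAULT_TARGET_DEPTH,
) -> np.ndarray:
    """Standardize depth then normalize/replicate: (D, H, W) -> (3, T, H, W)."""
    return preprocess_volume(standardize_slices(raw_volume, target_depth))


def model_input(
    raw_volume: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator = None,
    train_mode: bool = False,
    target_depth: int = DEFAULT_TARGET_DEPTH,
) -> np.ndarray:
    """Full chain raw (D, H, W) -> (3, target_depth, out_size, out_size)."""
    return augment_volume(preprocess_exam(raw_volume, target_depth), cfg, rng, train_mode)
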