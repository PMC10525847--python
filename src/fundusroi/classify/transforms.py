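"""Image preprocessing and online augmentation."""
from __future__ import annotations

from typing import Tuple

import numpy as np
from skimage.transform import resize, rotate


def apply_flip_rotation(image: np.ndarray, flip: bool, angle: float) -> np.ndarray:
    """Deterministic core of the augmentation: optional horizontal flip
    followed by rotation about the image center. ``angle == 0`` and
    ``flip == False`` is an exact identity."""
    out = image
    if flip:
        out = out[:, ::-1].copy()
    if angle != 0.0:
        out = rotate(out, angle, resize=False, mode="constant", cval=0.0,
                     preserve_range=True).astype(image.dtype, copy=False)
    return out


def draw_augment_params(rng: np.random.Generator) -> Tuple[bool, float]:
    """Flip with probability 1/2; rotation angle uniform on [-180, 180)."""
    flip = bool(rng.random() < 0.5)
    angle = float(rng.uniform(-180.0, 180.0))
    return flip, angle


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One online augmentation draw (fresh parameters per call)."""
    flip, angle = draw_augment_params(rng)
    return apply_flip_rotation(image, flip, angle)


def preprocess(
    image: np.ndarray,
    input_size: int,
    norm_mean: float = 0.5,
    norm_sd: float = 0.5,
) -> np.ndarray:
    """Resize to ``input_size`` square and normalize to (x - mean) / sd."""
    if input_size <= 0:
        raise ValueError("input_size must be positive")
    if norm_sd == 0:
        raise ValueError("norm_sd must be nonzero")
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] != (input_size, input_size):
        img = resize(img, (input_size, input_size) + img.shape[2:],
                     anti_aliasing=True, preserve_range=True)
    return ((img - norm_mean) / norm_sd).astype(np.float32)


def resize_to(image: np.ndarray, size: int) -> np.ndarray:
    """Plain resize keeping the [0, 1] range (no normalization)."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] == (size, size):
        return img.astype(np.float32)
    return resize(img, (size, size) + img.shape[2:], anti_aliasing=True,
                  preserve_range=True).astype(np.float32)
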