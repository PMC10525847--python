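"""Square region-of-interest extraction anchored to the optic-disc diagonal.

The two anatomical ROIs are squares: the optic-disc area has edge
``alpha * d`` centered at O, the macula area edge ``beta * d`` centered at M,
where ``d`` is the diagonal of the detected optic-disc box. Out-of-canvas
regions are constant-filled so the output shape is always exactly
``round(edge) x round(edge)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .landmarks import Landmarks


@dataclass(frozen=True)
class ROIConfig:
    alpha: float = 3.0   # optic-disc-area edge multiplier
    beta: float = 6.0    # macula-area edge multiplier
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class ROISet:
    od_roi: np.ndarray
    macula_roi: np.ndarray
    full: np.ndarray
    landmarks: Landmarks
    config: ROIConfig


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_square(
    image: np.ndarray,
    center: Tuple[float, float],
    edge: float,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Crop a square of side ``round(edge)`` centered at ``center`` (x, y).

    Pixels falling outside the canvas are set to ``fill_value``; the output is
    always exactly ``round(edge)`` per side. Works on 2-D (H, W) and 3-D
    (H, W, C) arrays.
    """
    e = round_half_up(edge)
    if e < 1:
        raise ValueError(f"edge must round to >= 1 pixel, got {edge}")
    cx, cy = center
    x0 = round_half_up(cx - e / 2.0)
    y0 = round_half_up(cy - e / 2.0)

    out_shape = (e, e) + image.shape[2:]
    out = np.full(out_shape, fill_value, dtype=image.dtype)
    h, w = image.shape[:2]
    sx0, sx1 = max(x0, 0), min(x0 + e, w)
    sy0, sy1 = max(y0, 0), min(y0 + e, h)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out


def make_rois(
    image: np.ndarray, landmarks: Landmarks, config: ROIConfig = ROIConfig()
) -> ROISet:
    """Extract the optic-disc and macula square ROIs plus the untouched image."""
    if landmarks.d <= 0:
        raise ValueError("landmarks.d must be positive")
    od = extract_square(image, landmarks.O, config.alpha * landmarks.d,
                        config.fill_value)
    mac = extract_square(image, landmarks.M, config.beta * landmarks.d,
                         config.fill_value)
    return ROISet(od_roi=od, macula_roi=mac, full=image, landmarks=landmarks,
                  config=config)
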