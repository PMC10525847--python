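"""Optic-disc / macula localization: detection records, proposal filtering,
and the one-box-per-class landmark selection rule.

The trainable detector itself is behind :class:`Detector`; the default
implementation is :class:`OracleDetector`, which reads synthetic ground truth
(optionally jittered) so the downstream geometry is testable without any
model training.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Type

import numpy as np

from .synthdata import SceneRecord
from .types import Box

DETECTION_CLASSES = ("optic_disc", "macula")


@dataclass(frozen=True)
class Detection:
    box: Box
    cls: str
    score: float

    def __post_init__(self) -> None:
        if self.cls not in DETECTION_CLASSES:
            raise ValueError(f"unknown detection class {self.cls!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class DetectorConfig:
    anchors_per_location: int = 9
    max_proposals: int = 256
    iou_elimination: float = 0.7

    def __post_init__(self) -> None:
        if self.anchors_per_location < 1 or self.max_proposals < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.iou_elimination < 1.0:
            raise ValueError("iou_elimination must be in (0, 1)")


@dataclass(frozen=True)
class Landmarks:
    """Optic-disc center O, macula center M, and the disc-box diagonal d —
    the scale unit for ROI extraction."""

    O: Tuple[float, float]
    M: Tuple[float, float]
    d: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("diagonal d must be positive")


class LandmarkNotFoundError(RuntimeError):
    def __init__(self, cls: str):
        super().__init__(f"landmark not found: no {cls!r} detection")
        self.cls = cls


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, symmetric."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def filter_proposals(
    proposals: Sequence[Detection],
    image_w: float,
    image_h: float,
    config: DetectorConfig = DetectorConfig(),
) -> List[Detection]:
    """Post-filter region proposals.

    1. Drop any proposal crossing the image boundary (any extent outside
       ``[0, W) x [0, H)``).
    2. Greedy suppression in descending score order: a proposal overlapping an
       already-kept one with IoU strictly above ``config.iou_elimination`` is
       eliminated (the lower-score member of the pair is the one dropped).
    3. Keep at most ``config.max_proposals``, by score.
    """
    in_bounds = [
        p for p in proposals
        if p.box.x0 >= 0 and p.box.y0 >= 0 and p.box.x1 <= image_w and p.box.y1 <= image_h
    ]
    # stable sort: ties preserve input order
    order = sorted(range(len(in_bounds)), key=lambda i: -in_bounds[i].score)
    kept: List[Detection] = []
    for i in order:
        cand = in_bounds[i]
        if all(iou(cand.box, k.box) <= config.iou_elimination for k in kept):
            kept.append(cand)
        if len(kept) >= config.max_proposals:
            break
    return kept


def select_landmarks(detections: Sequence[Detection]) -> Landmarks:
    """Pick the highest-score box per class (first occurrence wins ties);
    centers become O and M, and d is the chosen disc box's diagonal."""
    best: Dict[str, Detection] = {}
    for det in detections:
        cur = best.get(det.cls)
        if cur is None or det.score > cur.score:
            best[det.cls] = det
    for cls in DETECTION_CLASSES:
        if cls not in best:
            raise LandmarkNotFoundError(cls)
    disc = best["optic_disc"]
    mac = best["macula"]
    return Landmarks(O=disc.box.center, M=mac.box.center, d=disc.box.diagonal)


def oracle_detect(
    record: SceneRecord,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> List[Detection]:
    """Ground-truth-backed detector: returns the true disc and macula boxes
    with Gaussian corner jitter of ``jitter_sd`` pixels (0 -> exact), score 1.
    """
    if jitter_sd > 0 and rng is None:
        raise ValueError("rng required when jitter_sd > 0")

    def _jitter(box: Box) -> Box:
        if jitter_sd <= 0:
            return box
        dx0, dy0, dx1, dy1 = rng.normal(0.0, jitter_sd, size=4)
        x0, x1 = box.x0 + dx0, box.x1 + dx1
        y0, y1 = box.y0 + dy0, box.y1 + dy1
        if x1 <= x0:
            x0, x1 = min(x0, x1), min(x0, x1) + 1.0
        if y1 <= y0:
            y0, y1 = min(y0, y1), min(y0, y1) + 1.0
        return Box(x0, y0, x1, y1)

    return [
        Detection(_jitter(record.disc_box), "optic_disc", 1.0),
        Detection(_jitter(record.macula_box), "macula", 1.0),
    ]


class Detector:
    """Detector interface: a scene/image in, a list of detections out."""

    def detect(self, record: SceneRecord, rng: np.random.Generator) -> List[Detection]:
        raise NotImplementedError


class OracleDetector(Detector):
    def __init__(self, jitter_sd: float = 0.0):
        self.jitter_sd = jitter_sd

    def detect(self, record: SceneRecord, rng: np.random.Generator) -> List[Detection]:
        return oracle_detect(record, self.jitter_sd, rng)


DETECTOR_REGISTRY: Dict[str, Type[Detector]] = {"oracle": OracleDetector}


def detections_to_json(detections: Sequence[Detection]) -> str:
    return json.dumps(
        [
            {"cls": d.cls, "score": d.score, "x0": d.box.x0, "y0": d.box.y0,
             "x1": d.box.x1, "y1": d.box.y1}
            for d in detections
        ],
        sort_keys=True,
    )


def detections_from_json(text: str | Path) -> List[Detection]:
    data = json.loads(text)
    return [
        Detection(Box(r["x0"], r["y0"], r["x1"], r["y1"]), r["cls"], r["score"])
        for r in data
    ]
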