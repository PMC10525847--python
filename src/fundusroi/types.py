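"""Shared domain types: disease label vectors and pixel-coordinate boxes.

Coordinate convention used everywhere in this package: 0-based pixel
coordinates, min-inclusive / max-exclusive, ``x`` horizontal, ``y`` vertical.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

#: Canonical disease order. "Normal" is the derived all-zero state.
DISEASES: Tuple[str, ...] = ("dr", "rb", "rvo", "erm", "amd", "gs")

N_DISEASES = len(DISEASES)


@dataclass(frozen=True)
class LabelVector:
    """Six binary disease flags in canonical order (DR, RB, RVO, ERM, AMD, GS)."""

    dr: int
    rb: int
    rvo: int
    erm: int
    amd: int
    gs: int

    def __post_init__(self) -> None:
        for name in DISEASES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"label {name!r} must be 0 or 1, got {v!r}")

    @classmethod
    def from_sequence(cls, values: Sequence[int]) -> "LabelVector":
        if len(values) != N_DISEASES:
            raise ValueError(f"expected {N_DISEASES} labels, got {len(values)}")
        return cls(*(int(v) for v in values))

    def as_tuple(self) -> Tuple[int, ...]:
        return tuple(getattr(self, name) for name in DISEASES)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=np.int64)

    @property
    def is_normal(self) -> bool:
        """True iff no disease flag is set."""
        return not any(self.as_tuple())

    @property
    def n_positive(self) -> int:
        return int(sum(self.as_tuple()))


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle; min-inclusive/max-exclusive pixel extents."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box: ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)


def labels_to_matrix(labels: Iterable[LabelVector]) -> np.ndarray:
    """Stack label vectors into an (n, 6) int matrix in canonical order."""
    return np.asarray([lv.as_tuple() for lv in labels], dtype=np.int64)
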