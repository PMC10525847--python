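"""Synthetic widefield-fundus scene generator.

Produces grayscale retinal-looking images with a circular field, a bright
optic disc, a darker macula temporal to the disc, and disease-dependent
lesions whose spatial regime is configurable per disease:

* ``global``     — lesions scattered uniformly over the retinal field
                   (diabetic-retinopathy / retinal-break / vein-occlusion-like);
* ``macular``    — lesions concentrated around the macula center within a
                   radius expressed in units of the optic-disc box diagonal
                   ``d`` (epiretinal-membrane / macular-degeneration-like);
* ``peridiscal`` — lesions and a cup/ring perturbation confined to the optic
                   disc neighbourhood (glaucoma-suspect-like).

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
``(config, labels, seed)`` triple renders byte-identical images.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .types import DISEASES, Box, LabelVector

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image",
    *DISEASES,
    "disc_x0",
    "disc_y0",
    "disc_x1",
    "disc_y1",
    "mac_x0",
    "mac_y0",
    "mac_x1",
    "mac_y1",
]

SPATIAL_REGIMES = ("global", "macular", "peridiscal")


@dataclass(frozen=True)
class SpreadSpec:
    """Spatial regime of one disease's lesions.

    ``radius_d`` is the concentration radius in units of the optic-disc box
    diagonal ``d``; it is ignored for the ``global`` regime.
    """

    regime: str
    radius_d: float = 1.5

    def __post_init__(self) -> None:
        if self.regime not in SPATIAL_REGIMES:
            raise ValueError(f"unknown spatial regime {self.regime!r}")
        if self.radius_d <= 0:
            raise ValueError("radius_d must be positive")


def default_spread() -> Dict[str, SpreadSpec]:
    return {
        "dr": SpreadSpec("global"),
        "rb": SpreadSpec("global"),
        "rvo": SpreadSpec("global"),
        "erm": SpreadSpec("macular", 1.5),
        "amd": SpreadSpec("macular", 1.5),
        "gs": SpreadSpec("peridiscal", 1.0),
    }


# amplitude sign loosely mimics bright exudate/drusen-like vs dark
# haemorrhage/hole-like lesions; the pipeline only consumes spatial signal
LESION_AMPLITUDE = {
    "dr": 0.35,
    "rb": -0.35,
    "rvo": -0.30,
    "erm": -0.30,
    "amd": 0.35,
    "gs": -0.25,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic scene generator.

    All ``*_frac`` values are fractions of the image size (or half-size for
    radii), keeping the geometry resolution-independent.
    """

    image_size: int = 128
    field_radius_frac: float = 0.95
    disc_center_frac: Tuple[float, float] = (0.70, 0.50)
    disc_center_jitter_frac: float = 0.05
    disc_radius_frac: float = 0.042
    disc_aspect_jitter: float = 0.12
    macula_offset_frac: Tuple[float, float] = (-0.26, 0.0)
    macula_offset_jitter_frac: float = 0.08
    macula_radius_frac: float = 0.07
    prevalence: Tuple[float, ...] = (0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
    lesion_rate: float = 6.0
    lesion_sigma_frac: float = 0.014
    spread: Dict[str, SpreadSpec] = field(default_factory=default_spread)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for name in ("field_radius_frac", "disc_radius_frac", "macula_radius_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if len(self.prevalence) != len(DISEASES):
            raise ValueError("prevalence must have six entries")
        for p in self.prevalence:
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        if self.lesion_rate < 0:
            raise ValueError("lesion_rate must be >= 0")
        for name in DISEASES:
            if name not in self.spread:
                raise ValueError(f"spread missing disease {name!r}")
        # disc and macula centers must fall inside the retinal field even at
        # maximal jitter
        half = self.image_size / 2.0
        r_field = self.field_radius_frac * half
        for label, (cx, cy) in (
            ("disc", self._nominal_disc_center()),
            ("macula", self._nominal_macula_center()),
        ):
            slack = (self.disc_center_jitter_frac + self.macula_offset_jitter_frac) \
                * self.image_size
            dist = math.hypot(cx - half, cy - half)
            if dist + slack > r_field:
                raise ValueError(f"{label} center can leave the retinal field")

    def _nominal_disc_center(self) -> Tuple[float, float]:
        fx, fy = self.disc_center_frac
        return fx * self.image_size, fy * self.image_size

    def _nominal_macula_center(self) -> Tuple[float, float]:
        cx, cy = self._nominal_disc_center()
        ox, oy = self.macula_offset_frac
        return cx + ox * self.image_size, cy + oy * self.image_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spread"] = {
            k: {"regime": v.regime, "radius_d": v.radius_d}
            for k, v in self.spread.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "spread" in d:
            d["spread"] = {k: SpreadSpec(**v) for k, v in d["spread"].items()}
        for key in ("disc_center_frac", "macula_offset_frac", "prevalence"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SceneRecord:
    """Ground truth for one rendered scene."""

    image_path: Optional[str]
    labels: LabelVector
    disc_box: Box
    macula_box: Box
    lesion_centers: List[Tuple[str, float, float]]


def sample_label_vector(
    prevalence: Sequence[float], rng: np.random.Generator
) -> LabelVector:
    """Draw six independent Bernoulli disease flags.

    The all-zero outcome is the Normal state.
    """
    if len(prevalence) != len(DISEASES):
        raise ValueError("prevalence must have six entries")
    for p in prevalence:
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence {p} outside [0, 1]")
    draws = rng.random(len(DISEASES)) < np.asarray(prevalence, dtype=float)
    return LabelVector.from_sequence(draws.astype(int))


def _add_gaussian_blob(
    canvas: np.ndarray, cx: float, cy: float, sigma_x: float, sigma_y: float,
    amplitude: float,
) -> None:
    """Add an elliptical Gaussian profile in place, windowed to 4 sigma."""
    size = canvas.shape[0]
    x0 = max(0, int(cx - 4 * sigma_x))
    x1 = min(size, int(cx + 4 * sigma_x) + 2)
    y0 = max(0, int(cy - 4 * sigma_y))
    y1 = min(size, int(cy + 4 * sigma_y) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    ys = np.arange(y0, y1, dtype=float)[:, None]
    xs = np.arange(x0, x1, dtype=float)[None, :]
    profile = np.exp(
        -((xs - cx) ** 2 / (2 * sigma_x**2) + (ys - cy) ** 2 / (2 * sigma_y**2))
    )
    canvas[y0:y1, x0:x1] += amplitude * profile


def _sample_in_disk(
    rng: np.random.Generator, cx: float, cy: float, radius: float
) -> Tuple[float, float]:
    theta = rng.uniform(0.0, 2 * math.pi)
    r = radius * math.sqrt(rng.random())
    return cx + r * math.cos(theta), cy + r * math.sin(theta)


def _sample_truncated_gaussian(
    rng: np.random.Generator, cx: float, cy: float, radius: float,
    field_center: Tuple[float, float], field_radius: float,
) -> Tuple[float, float]:
    """Gaussian (sd = radius/2) around (cx, cy), rejected outside the radius
    and outside the retinal field."""
    sd = radius / 2.0
    fx, fy = field_center
    for _ in range(1000):
        x = rng.normal(cx, sd)
        y = rng.normal(cy, sd)
        if math.hypot(x - cx, y - cy) <= radius and \
                math.hypot(x - fx, y - fy) <= field_radius:
            return x, y
    # pathological configuration; fall back to the anchor itself
    return cx, cy


def render_scene(
    config: SyntheticConfig, labels: LabelVector, rng: np.random.Generator
) -> Tuple[np.ndarray, SceneRecord]:
    """Render one scene.

    Returns the uint8 grayscale image and its :class:`SceneRecord` (with
    ``image_path`` unset; :func:`generate_dataset` fills it in after writing).
    """
    size = config.image_size
    half = size / 2.0
    field_radius = config.field_radius_frac * half

    canvas = np.zeros((size, size), dtype=float)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    in_field = (xs - half) ** 2 + (ys - half) ** 2 <= field_radius**2
    canvas[in_field] = 0.40

    # optic disc: bright ellipse with jittered center and aspect
    dcx, dcy = config._nominal_disc_center()
    jit = config.disc_center_jitter_frac * size
    dcx += rng.uniform(-jit, jit)
    dcy += rng.uniform(-jit, jit)
    r_base = config.disc_radius_frac * size
    rx = r_base * (1 + rng.uniform(-config.disc_aspect_jitter, config.disc_aspect_jitter))
    ry = r_base * (1 + rng.uniform(-config.disc_aspect_jitter, config.disc_aspect_jitter))
    _add_gaussian_blob(canvas, dcx, dcy, rx / 1.5, ry / 1.5, 0.45)
    disc_box = Box(dcx - rx, dcy - ry, dcx + rx, dcy + ry)
    d = disc_box.diagonal

    # physiological cup: faint central darkening; enlarged and deepened when
    # the peridiscal disease is active so only the disc neighbourhood carries
    # the discriminative signal
    cup_amp, cup_frac = (-0.55, 0.60) if labels.gs else (-0.15, 0.30)
    _add_gaussian_blob(canvas, dcx, dcy, cup_frac * rx, cup_frac * ry, cup_amp)

    # macula: darker blob temporal to the disc
    ox, oy = config.macula_offset_frac
    mjit = config.macula_offset_jitter_frac * size
    mcx = dcx + ox * size + rng.uniform(-mjit, mjit)
    mcy = dcy + oy * size + rng.uniform(-mjit, mjit)
    mr = config.macula_radius_frac * size
    _add_gaussian_blob(canvas, mcx, mcy, mr / 1.5, mr / 1.5, -0.12)
    macula_box = Box(mcx - mr, mcy - mr, mcx + mr, mcy + mr)

    lesion_sigma = config.lesion_sigma_frac * size
    lesion_centers: List[Tuple[str, float, float]] = []
    field_center = (half, half)
    for name in DISEASES:
        if not getattr(labels, name):
            continue
        spec = config.spread[name]
        n_lesions = int(rng.poisson(config.lesion_rate))
        if spec.regime == "global":
            anchor, radius = field_center, field_radius
        elif spec.regime == "macular":
            anchor, radius = (mcx, mcy), spec.radius_d * d
        else:  # peridiscal
            anchor, radius = (dcx, dcy), spec.radius_d * d
        if spec.regime != "global" and radius > field_radius:
            logger.warning(
                "%s regime radius %.1f px exceeds field radius %.1f px; clipping",
                name, radius, field_radius,
            )
            radius = field_radius
        for _ in range(n_lesions):
            if spec.regime == "global":
                x, y = _sample_in_disk(rng, *anchor, radius)
            else:
                x, y = _sample_truncated_gaussian(
                    rng, *anchor, radius, field_center, field_radius
                )
            lesion_centers.append((name, x, y))
            _add_gaussian_blob(
                canvas, x, y, lesion_sigma, lesion_sigma, LESION_AMPLITUDE[name]
            )

    if config.noise_sd > 0:
        canvas += rng.normal(0.0, config.noise_sd, size=canvas.shape)

    image = (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    record = SceneRecord(
        image_path=None,
        labels=labels,
        disc_box=disc_box,
        macula_box=macula_box,
        lesion_centers=lesion_centers,
    )
    return image, record


def generate_dataset(
    config: SyntheticConfig,
    n_images: int,
    out_dir: Path | str,
    overwrite: bool = False,
) -> Path:
    """Render ``n_images`` scenes into ``out_dir`` and write the manifest.

    Layout: ``images/img_00000.png`` ..., ``manifest.csv`` with the columns of
    :data:`MANIFEST_COLUMNS`, and ``config.json`` recording the full generator
    configuration (seed included). Returns the manifest path.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} already exists")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_images):
        labels = sample_label_vector(config.prevalence, rng)
        image, record = render_scene(config, labels, rng)
        rel = f"images/img_{i:05d}.png"
        path = out_dir / rel
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} already exists")
        Image.fromarray(image, mode="L").save(path, format="PNG")
        record.image_path = rel
        rows.append(
            [rel, *labels.as_tuple(),
             *(round(v, 4) for v in record.disc_box.as_tuple()),
             *(round(v, 4) for v in record.macula_box.as_tuple())]
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    sidecar = {"config": config.to_dict(), "n_images": n_images}
    (out_dir / "config.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return manifest_path


def load_manifest(manifest_path: Path | str) -> pd.DataFrame:
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def record_from_row(row: pd.Series) -> SceneRecord:
    """Rehydrate a SceneRecord (minus lesion centers) from a manifest row."""
    return SceneRecord(
        image_path=str(row["image"]),
        labels=LabelVector.from_sequence([int(row[d]) for d in DISEASES]),
        disc_box=Box(row["disc_x0"], row["disc_y0"], row["disc_x1"], row["disc_y1"]),
        macula_box=Box(row["mac_x0"], row["mac_y0"], row["mac_x1"], row["mac_y1"]),
        lesion_centers=[],
    )


def load_image(base_dir: Path | str, rel_path: str) -> np.ndarray:
    """Load a dataset image as a float array in [0, 1]."""
    arr = np.asarray(Image.open(Path(base_dir) / rel_path).convert("L"))
    return arr.astype(np.float32) / 255.0
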