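"""Synthetic four-class texture image generator and dataset I/O.

The study data are H&E-stained photomicrographs of pediatric medulloblastoma,
labeled with one of four histological subtypes (classic, desmoplastic,
large_cell, nodular).  This module provides a synthetic stand-in: four
texture-distinguishable image classes whose inter-class contrast is
controlled by a single ``separability`` knob, so the full pipeline
(texture matrices, deep features, fusion, classification) is exercisable
and testable without any external download.

Each class is produced by a distinct stationary texture process layered on a
shared correlated-noise baseline:

* ``classic``       — Gaussian random field whose correlation length grows
                      with separability (smooth, cloudy texture),
* ``desmoplastic``  — oriented sinusoidal stripes (band-like texture),
* ``large_cell``    — Poisson-placed dark blobs on a bright background
                      (nodule-like texture),
* ``nodular``       — fine-grain speckle (high-frequency texture).

At ``separability = 0`` every class collapses onto the shared baseline
process, so class labels carry no textural information; at 1 the four
processes are maximally distinct.  Grayscale textures are tinted with a
two-tone H&E-like colormap to yield RGB images, matching what the real
pipeline consumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LABELS",
    "SyntheticSpec",
    "LabeledImage",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Fixed four-class label vocabulary, in canonical order.
LABELS: tuple[str, ...] = ("classic", "desmoplastic", "large_cell", "nodular")

# H&E-like two-tone colormap endpoints (dark hematoxylin purple -> light
# eosin pink), as float RGB in [0, 1].
_HE_DARK = np.array([0.33, 0.15, 0.45])
_HE_LIGHT = np.array([0.95, 0.82, 0.88])

_DEFAULT_TEXTURE_PARAMS: dict[str, dict[str, float]] = {
    "classic": {"base_sigma": 2.0, "long_sigma": 10.0},
    "desmoplastic": {"stripe_period": 12.0, "stripe_angle_deg": 30.0},
    "large_cell": {"blob_density": 4e-3, "blob_radius": 5.0},
    "nodular": {"speckle_fraction": 1.0},
}
_NOISE_LEVEL = 0.06


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset draw.

    Parameters
    ----------
    n_per_class
        Number of images for each of the four classes, in ``LABELS`` order.
        Default mirrors the study's 59/42/30/23 class distribution.
    image_size
        ``(height, width)`` in pixels.
    separability
        Scalar in [0, 1] scaling inter-class texture contrast; 0 draws all
        classes from one process, 1 gives maximally distinct textures.
    texture_params
        Optional per-class overrides of the generator parameters.
    seed
        Base seed; identical spec + seed gives a bit-identical image set.
    """

    n_per_class: tuple[int, int, int, int] = (59, 42, 30, 23)
    image_size: tuple[int, int] = (256, 256)
    separability: float = 1.0
    texture_params: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(LABELS):
            raise ValueError(
                f"n_per_class must have exactly {len(LABELS)} entries, "
                f"got {len(self.n_per_class)}"
            )
        if any(int(n) < 1 for n in self.n_per_class):
            raise ValueError(f"all class counts must be >= 1, got {self.n_per_class}")
        if not (0.0 <= self.separability <= 1.0):
            raise ValueError(f"separability must be in [0, 1], got {self.separability}")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError(f"image_size entries must be positive, got {self.image_size}")

    def params_for(self, label: str) -> dict[str, float]:
        merged = dict(_DEFAULT_TEXTURE_PARAMS[label])
        merged.update(self.texture_params.get(label, {}))
        return merged


@dataclass
class LabeledImage:
    """An RGB image with its class label and provenance identifiers."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    image_id: str
    parent_id: str | None = None  # set on augmented copies

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")


def _baseline_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Correlated Gaussian random field, approximately zero-mean unit-variance."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        f = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    else:
        f = noise
    sd = f.std()
    return f / sd if sd > 0 else f


def _render_class_texture(
    label: str,
    rng: np.random.Generator,
    shape: tuple[int, int],
    s: float,
    params: Mapping[str, float],
) -> np.ndarray:
    """Grayscale texture in [0, 1] for one class at separability ``s``."""
    h, w = shape
    base_sigma = float(_DEFAULT_TEXTURE_PARAMS["classic"]["base_sigma"])

    if label == "classic":
        sigma = base_sigma + s * (float(params["long_sigma"]) - base_sigma)
        tex = _baseline_field(rng, shape, sigma)
    elif label == "desmoplastic":
        tex = _baseline_field(rng, shape, base_sigma)
        theta = np.deg2rad(float(params["stripe_angle_deg"]))
        yy, xx = np.mgrid[0:h, 0:w]
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(
            2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / float(params["stripe_period"])
            + phase
        )
        tex = (1 - s) * tex + s * (1.6 * carrier + 0.4 * tex)
    elif label == "large_cell":
        tex = _baseline_field(rng, shape, base_sigma)
        density = float(params["blob_density"])
        radius = float(params["blob_radius"])
        n_blobs = rng.poisson(density * h * w)
        mask = np.zeros(shape)
        if n_blobs > 0:
            cy = rng.uniform(0, h, n_blobs)
            cx = rng.uniform(0, w, n_blobs)
            yy, xx = np.mgrid[0:h, 0:w]
            for y0, x0 in zip(cy, cx):
                r2 = (yy - y0) ** 2 + (xx - x0) ** 2
                mask = np.maximum(mask, np.exp(-r2 / (2 * radius**2)))
        # dark blobs on a bright background
        tex = (1 - s) * tex + s * (1.2 - 3.2 * mask)
    elif label == "nodular":
        fine = rng.standard_normal(shape)
        coarse = _baseline_field(rng, shape, base_sigma)
        frac = s * float(params["speckle_fraction"])
        tex = (1 - frac) * coarse + frac * 1.4 * fine
    else:  # pragma: no cover - guarded by LABELS check upstream
        raise ValueError(f"unknown label {label!r}")

    tex = tex + _NOISE_LEVEL * rng.standard_normal(shape)
    # map ~N(0,1) amplitudes into [0,1] with a fixed affine + clip, so the
    # normalization itself does not depend on the realization
    return np.clip(0.5 + 0.22 * tex, 0.0, 1.0)


def _tint_he(gray: np.ndarray) -> np.ndarray:
    """Map grayscale [0,1] to an H&E-like purple-to-pink RGB uint8 image."""
    rgb = _HE_DARK[None, None, :] + gray[..., None] * (_HE_LIGHT - _HE_DARK)[None, None, :]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> list[LabeledImage]:
    """Generate the labeled synthetic image set described by ``spec``.

    Returns exactly ``sum(spec.n_per_class)`` images; class ``i`` appears
    ``spec.n_per_class[i]`` times.  Per-image random substreams are derived
    from ``(spec.seed, counter)`` so the output is independent of generation
    order and bit-identical across runs for the same spec.
    """
    images: list[LabeledImage] = []
    counter = 0
    for label, n in zip(LABELS, spec.n_per_class):
        params = spec.params_for(label)
        for k in range(int(n)):
            rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, counter])
            gray = _render_class_texture(
                label, rng, tuple(spec.image_size), float(spec.separability), params
            )
            images.append(
                LabeledImage(
                    pixels=_tint_he(gray),
                    label=label,
                    image_id=f"{label}_{k:04d}",
                )
            )
            counter += 1
    return images


def write_dataset(images: Sequence[LabeledImage], out_dir: str | Path) -> Path:
    """Write PNGs under per-class subdirectories plus a CSV manifest.

    Returns the manifest path.  An empty image list yields an empty manifest
    (header only) and no image files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    rows = []
    for img in images:
        class_dir = out_dir / img.label
        class_dir.mkdir(exist_ok=True)
        rel = Path(img.label) / f"{img.image_id}.png"
        Image.fromarray(img.pixels).save(out_dir / rel, format="PNG")
        rows.append((img.image_id, str(rel), img.label))
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "path", "label"])
        writer.writerows(rows)
    return manifest_path


def read_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a dataset written by :func:`write_dataset` (lossless round-trip)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    images: list[LabeledImage] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            with Image.open(root / row["path"]) as im:
                pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
            images.append(
                LabeledImage(pixels=pixels, label=row["label"], image_id=row["image_id"])
            )
    return images
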