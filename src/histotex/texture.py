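"""Gray-level co-occurrence (GLCM) and run-length (GLRM) texture analysis.

Both statistics operate on a quantized grayscale image with ``G`` gray
levels (default 8, the value the pipeline uses throughout):

* GLCM: a ``G x G`` matrix counting directed pixel pairs ``(p, p + offset)``
  whose gray levels are ``(i, j)``, for an offset defined by an orientation
  theta in {0, 45, 90, 135} degrees and a distance ``d``.  Normalizing by the
  number of valid pairs turns the counts into a joint probability
  distribution over level pairs — a second-order texture statistic.
* GLRM: a ``G x L`` matrix whose entry ``Q[m][n]`` counts maximal runs of
  ``n`` consecutive pixels at level ``m`` along a scan direction — a
  higher-order statistic sensitive to streaky vs. granular texture.

The matrices computed at the four orientations are rendered into "textural
images": RGB heatmaps sized for a CNN input layer, which downstream stages
treat exactly like ordinary photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import matplotlib
import numpy as np
from PIL import Image

from .datasets import LabeledImage

__all__ = [
    "ORIENTATIONS",
    "QuantizedImage",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "TexturalImage",
    "quantize",
    "compute_glcm",
    "compute_glrm",
    "render_textural_image",
    "texturize_image",
]

#: Supported scan orientations, degrees.
ORIENTATIONS: tuple[int, ...] = (0, 45, 90, 135)

# Directed (row, col) pixel offsets per orientation for distance d, following
# the usual image convention (row axis points down): 0 deg looks right,
# 90 deg looks up.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_LUMA = np.array([0.299, 0.587, 0.114])

_DEFAULT_COLORMAP = "viridis"

RenderMode = Literal["matrix", "tiled", "local"]


@dataclass
class QuantizedImage:
    """An ``N x M`` integer grid of gray levels in ``[0, G-1]``."""

    levels: np.ndarray
    G: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.ndim != 2 or self.levels.size == 0:
            raise ValueError(f"levels must be a non-empty 2-D grid, got shape {self.levels.shape}")
        if self.G < 2:
            raise ValueError(f"G must be >= 2, got {self.G}")
        lo, hi = int(self.levels.min()), int(self.levels.max())
        if lo < 0 or hi >= self.G:
            raise ValueError(f"levels must lie in [0, {self.G - 1}], observed range [{lo}, {hi}]")


@dataclass
class CooccurrenceMatrix:
    """Directed gray-level pair counts at one orientation and distance."""

    counts: np.ndarray  # G x G non-negative ints
    theta: int
    distance: int = 1
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        total = int(self.counts.sum())
        if total > 0:
            self.normalized = self.counts / total
        else:
            self.normalized = np.zeros_like(self.counts, dtype=float)


@dataclass
class RunLengthMatrix:
    """Maximal-run counts ``Q[m][n-1]`` = runs of level ``m``, length ``n``.

    Column ``j`` holds runs of length ``j + 1``; ``L = max(N, M)`` columns are
    always allocated so the matrix shape is predictable regardless of the
    realized maximum run length.
    """

    Q: np.ndarray  # G x L non-negative ints
    theta: int
    L: int

    @property
    def normalized(self) -> np.ndarray:
        total = int(self.Q.sum())
        return self.Q / total if total > 0 else np.zeros_like(self.Q, dtype=float)


@dataclass
class TexturalImage:
    """RGB heatmap rendering of texture matrices, sized for a CNN input."""

    pixels: np.ndarray  # H x W x 3 uint8
    method: Literal["glcm", "glrm"]
    source_id: str
    render_mode: RenderMode = "matrix"


def quantize(image: LabeledImage | np.ndarray, G: int = 8) -> QuantizedImage:
    """Convert to grayscale and bin intensities into ``G`` uniform levels.

    Grayscale uses the Rec. 601 luminance weights (0.299, 0.587, 0.114);
    the intensity range [0, 255] is split into ``G`` equal-width bins, so a
    value ``v`` maps to level ``floor(v * G / 256)``.  ``G = 256`` is the
    identity on grayscale input.
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    if isinstance(image, LabeledImage):
        pixels, source_id = image.pixels, image.image_id
    else:
        pixels, source_id = np.asarray(image), ""
    if pixels.ndim == 3:
        gray = pixels.astype(float) @ _LUMA
    elif pixels.ndim == 2:
        gray = pixels.astype(float)
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {pixels.shape}")
    # round away float dust (the luma weights sum to 1 - 1e-16, so an exact
    # gray value v would otherwise land a hair under its bin edge)
    gray = np.round(gray, 6)
    levels = np.clip(np.floor(gray * G / 256.0).astype(np.int64), 0, G - 1)
    return QuantizedImage(levels=levels, G=G, source_id=source_id)


def compute_glcm(
    q: QuantizedImage, theta: int, distance: int = 1, symmetric: bool = False
) -> CooccurrenceMatrix:
    """Count directed gray-level pairs at orientation ``theta`` (degrees).

    ``counts[i, j]`` is the number of pixel pairs ``(p, p + offset)`` with
    levels ``(i, j)``, where ``offset`` is ``(0, +d)`` at 0 deg, ``(-d, +d)``
    at 45, ``(-d, 0)`` at 90 and ``(-d, -d)`` at 135; pairs whose neighbor
    falls outside the grid are skipped.  With ``symmetric=True`` each pair is
    also accumulated in the reverse direction (counts become symmetric).
    """
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ORIENTATIONS}, got {theta}")
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    dr, dc = (o * distance for o in _OFFSETS[theta])
    n, m = q.levels.shape

    # crop to the overlap of the grid with its shifted copy
    r0, r1 = max(0, -dr), min(n, n - dr)
    c0, c1 = max(0, -dc), min(m, m - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"distance {distance} leaves no valid pixel pairs at theta={theta} "
            f"for a {n}x{m} image"
        )
    ref = q.levels[r0:r1, c0:c1]
    nbr = q.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    flat = ref.ravel() * q.G + nbr.ravel()
    counts = np.bincount(flat, minlength=q.G * q.G).reshape(q.G, q.G)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts=counts, theta=theta, distance=distance)


def _run_lengths(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Levels and lengths of the maximal runs along a 1-D line."""
    if line.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [line.size]))
    return line[starts], ends - starts


def _scan_lines(levels: np.ndarray, theta: int):
    """Yield the 1-D scan lines of the grid for orientation ``theta``.

    0 deg scans rows, 90 deg columns, 45 deg anti-diagonals (direction
    (-1, +1)) and 135 deg main diagonals (direction (-1, -1)); every pixel
    belongs to exactly one line per orientation.
    """
    n, m = levels.shape
    if theta == 0:
        yield from levels
    elif theta == 90:
        yield from levels.T
    elif theta == 135:
        for off in range(-(n - 1), m):
            yield np.diagonal(levels, offset=off)
    elif theta == 45:
        flipped = levels[::-1]
        for off in range(-(n - 1), m):
            yield np.diagonal(flipped, offset=off)
    else:
        raise ValueError(f"theta must be one of {ORIENTATIONS}, got {theta}")


def compute_glrm(q: QuantizedImage, theta: int) -> RunLengthMatrix:
    """Count maximal same-level runs along direction ``theta``.

    Every maximal run of ``n`` pixels at level ``m`` increments ``Q[m][n]``.
    Since the scan lines partition the grid, ``sum_{m,n} n * Q[m][n]`` equals
    the pixel count ``N * M`` for every orientation.
    """
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ORIENTATIONS}, got {theta}")
    n, m = q.levels.shape
    L = max(n, m)
    Q = np.zeros((q.G, L), dtype=np.int64)
    for line in _scan_lines(q.levels, theta):
        lv, ln = _run_lengths(np.ascontiguousarray(line))
        np.add.at(Q, (lv, ln - 1), 1)
    return RunLengthMatrix(Q=Q, theta=theta, L=L)


def _colormap_rgb(values: np.ndarray, colormap: str) -> np.ndarray:
    """Map an array in [0, 1] through a matplotlib colormap to uint8 RGB."""
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(np.clip(values, 0.0, 1.0))
    return np.clip(np.round(rgba[..., :3] * 255.0), 0, 255).astype(np.uint8)


def _minmax(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant array renders mid-colormap (no NaNs)."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def _resize_nearest(rgb: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    h, w = target_size
    im = Image.fromarray(rgb).resize((w, h), Image.NEAREST)
    return np.asarray(im, dtype=np.uint8)


def _matrix_of(mat: CooccurrenceMatrix | RunLengthMatrix) -> np.ndarray:
    return np.asarray(mat.normalized, dtype=float)


def _glcm_contrast(p: np.ndarray) -> float:
    g = p.shape[0]
    i, j = np.mgrid[0:g, 0:g]
    return float(((i - j) ** 2 * p).sum())


def _glrm_short_run_emphasis(q: np.ndarray) -> float:
    total = q.sum()
    if total == 0:
        return 0.0
    n = np.arange(1, q.shape[1] + 1, dtype=float)
    return float((q / n[None, :] ** 2).sum() / total)


def render_textural_image(
    matrices: Sequence[CooccurrenceMatrix | RunLengthMatrix],
    method: Literal["glcm", "glrm"],
    render_mode: RenderMode = "matrix",
    target_size: tuple[int, int] = (224, 224),
    colormap: str = _DEFAULT_COLORMAP,
    source_id: str = "",
    quantized: QuantizedImage | None = None,
    window: int = 32,
    stride: int = 16,
) -> TexturalImage:
    """Render four per-orientation texture matrices as one RGB heatmap.

    Modes
    -----
    ``matrix`` (default)
        Element-wise mean of the four normalized matrices, min-max scaled to
        [0, 1], colormapped, then nearest-neighbor upsampled to
        ``target_size``.
    ``tiled``
        Each orientation rendered separately and arranged in a 2x2 grid.
    ``local``
        Spatially-resolved map: a sliding window over the quantized image
        (``quantized`` required) computes a per-orientation summary statistic
        (GLCM contrast or GLRM short-run emphasis), the orientation mean of
        which is colormapped.  Preserves where texture varies in the image at
        the cost of discarding the full gray-level structure.

    Rendering is fully deterministic: identical inputs give identical pixels.
    """
    if len(matrices) != len(ORIENTATIONS):
        raise ValueError(f"expected {len(ORIENTATIONS)} matrices (one per orientation), got {len(matrices)}")
    thetas = sorted(m.theta for m in matrices)
    if thetas != sorted(ORIENTATIONS):
        raise ValueError(f"matrices must cover orientations {ORIENTATIONS}, got {thetas}")
    shapes = {m.normalized.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"matrices have mismatched shapes: {sorted(shapes)}")

    ordered = sorted(matrices, key=lambda m: m.theta)
    if render_mode == "matrix":
        mean = np.mean([_matrix_of(m) for m in ordered], axis=0)
        rgb = _colormap_rgb(_minmax(mean), colormap)
        pixels = _resize_nearest(rgb, target_size)
    elif render_mode == "tiled":
        tiles = [_colormap_rgb(_minmax(_matrix_of(m)), colormap) for m in ordered]
        top = np.concatenate(tiles[:2], axis=1)
        bottom = np.concatenate(tiles[2:], axis=1)
        pixels = _resize_nearest(np.concatenate([top, bottom], axis=0), target_size)
    elif render_mode == "local":
        if quantized is None:
            raise ValueError("render_mode='local' requires the quantized source image")
        stat = _glcm_contrast if method == "glcm" else _glrm_short_run_emphasis
        n, m_ = quantized.levels.shape
        win = min(window, n, m_)
        rows = range(0, max(n - win, 0) + 1, stride)
        cols = range(0, max(m_ - win, 0) + 1, stride)
        field_maps = []
        for theta in ORIENTATIONS:
            grid = np.zeros((len(rows), len(cols)))
            for ri, r in enumerate(rows):
                for ci, c in enumerate(cols):
                    patch = QuantizedImage(
                        levels=quantized.levels[r : r + win, c : c + win], G=quantized.G
                    )
                    if method == "glcm":
                        grid[ri, ci] = stat(compute_glcm(patch, theta).normalized)
                    else:
                        grid[ri, ci] = stat(compute_glrm(patch, theta).Q)
            field_maps.append(grid)
        rgb = _colormap_rgb(_minmax(np.mean(field_maps, axis=0)), colormap)
        pixels = _resize_nearest(rgb, target_size)
    else:
        raise ValueError(f"unknown render_mode {render_mode!r}")

    return TexturalImage(pixels=pixels, method=method, source_id=source_id, render_mode=render_mode)


def texturize_image(
    image: LabeledImage,
    method: Literal["glcm", "glrm"],
    G: int = 8,
    distance: int = 1,
    render_mode: RenderMode = "matrix",
    target_size: tuple[int, int] = (224, 224),
    colormap: str = _DEFAULT_COLORMAP,
    window: int = 32,
    stride: int = 16,
) -> LabeledImage:
    """Quantize an image, compute its four-orientation texture matrices and
    render them as a textural image carrying the source label."""
    q = quantize(image, G=G)
    if method == "glcm":
        mats: list[CooccurrenceMatrix | RunLengthMatrix] = [
            compute_glcm(q, theta, distance=distance) for theta in ORIENTATIONS
        ]
    elif method == "glrm":
        mats = [compute_glrm(q, theta) for theta in ORIENTATIONS]
    else:
        raise ValueError(f"method must be 'glcm' or 'glrm', got {method!r}")
    rendered = render_textural_image(
        mats,
        method=method,
        render_mode=render_mode,
        target_size=target_size,
        colormap=colormap,
        source_id=image.image_id,
        quantized=q,
        window=window,
        stride=stride,
    )
    return LabeledImage(
        pixels=rendered.pixels,
        label=image.label,
        image_id=f"{image.image_id}",
        parent_id=image.parent_id,
    )
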