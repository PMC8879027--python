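"""Two-step concatenation fusion of deep feature vectors.

Step 1 fuses the two textural deep-feature vectors of an image (GLCM then
GLRM, each of length ``n_classes``) into one vector of length 8 under the
4-class defaults.  Step 2 prepends the spatial deep features extracted from
the original image, giving the full fused descriptor of length 12.  Fusion
is plain concatenation — no rescaling — so output length is exactly the sum
of component lengths and every input coordinate appears exactly once.
Fusion is within-backbone: the spatial, GLCM and GLRM vectors must all come
from the same architecture (trained on the three image kinds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .features import DeepFeatureVector

__all__ = ["FusedFeatureVector", "fuse_textural", "fuse_full", "build_feature_table"]

#: Canonical component order for the full fusion: spatial first, then textural.
KIND_ORDER = ("original", "glcm", "glrm")


@dataclass
class FusedFeatureVector:
    """Concatenated features with ordered (backbone, image_kind) provenance."""

    values: np.ndarray
    components: tuple[tuple[str, str], ...]  # ordered (backbone, image_kind)
    fusion_step: Literal["textural", "full"]
    image_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.components:
            raise ValueError("provenance component list must be non-empty")
        if len(set(self.components)) != len(self.components):
            raise ValueError(f"duplicate provenance components: {self.components}")


def _check_pair(a: DeepFeatureVector, b: DeepFeatureVector | FusedFeatureVector) -> None:
    if a.image_id != b.image_id:
        raise ValueError(f"image_id mismatch: {a.image_id!r} vs {b.image_id!r}")


def fuse_textural(f_glcm: DeepFeatureVector, f_glrm: DeepFeatureVector) -> FusedFeatureVector:
    """Fusion step 1: concatenate GLCM then GLRM deep features (length 8
    under the 4-class defaults)."""
    _check_pair(f_glcm, f_glrm)
    if f_glcm.backbone_name != f_glrm.backbone_name:
        raise ValueError(
            f"fusion is within-backbone: {f_glcm.backbone_name!r} vs {f_glrm.backbone_name!r}"
        )
    if f_glcm.image_kind != "glcm" or f_glrm.image_kind != "glrm":
        raise ValueError(
            f"expected image_kinds ('glcm', 'glrm'), got "
            f"({f_glcm.image_kind!r}, {f_glrm.image_kind!r})"
        )
    return FusedFeatureVector(
        values=np.concatenate([f_glcm.values, f_glrm.values]),
        components=((f_glcm.backbone_name, "glcm"), (f_glrm.backbone_name, "glrm")),
        fusion_step="textural",
        image_id=f_glcm.image_id,
        label=f_glcm.label or f_glrm.label,
    )


def fuse_full(f_spatial: DeepFeatureVector, fused_textural: FusedFeatureVector) -> FusedFeatureVector:
    """Fusion step 2: spatial features first, then the fused textural block
    (length 12 under the 4-class defaults)."""
    _check_pair(f_spatial, fused_textural)
    if f_spatial.image_kind != "original":
        raise ValueError(f"spatial features must have image_kind 'original', got {f_spatial.image_kind!r}")
    if fused_textural.fusion_step != "textural":
        raise ValueError("second argument must be a step-1 (textural) fusion")
    backbones = {b for b, _ in fused_textural.components}
    if backbones != {f_spatial.backbone_name}:
        raise ValueError(
            f"fusion is within-backbone: spatial from {f_spatial.backbone_name!r}, "
            f"textural from {sorted(backbones)}"
        )
    return FusedFeatureVector(
        values=np.concatenate([f_spatial.values, fused_textural.values]),
        components=((f_spatial.backbone_name, "original"), *fused_textural.components),
        fusion_step="full",
        image_id=f_spatial.image_id,
        label=f_spatial.label or fused_textural.label,
    )


def build_feature_table(
    features: Iterable[DeepFeatureVector],
    fusion_step: Literal["textural", "full", None] = None,
    image_kind: str = "original",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble a per-image feature matrix and aligned label vector.

    ``fusion_step=None`` selects the single ``image_kind`` vectors
    (``n x 4`` under defaults); ``"textural"`` builds step-1 fusions
    (``n x 8``); ``"full"`` builds step-2 fusions (``n x 12``).  Rows are
    sorted by ``image_id`` and columns named
    ``<backbone>.<kind>.f<i>``, so the table is invariant to the order the
    feature vectors are supplied in.  A missing component vector raises an
    error naming the offending image.
    """
    by_image: dict[str, dict[str, DeepFeatureVector]] = {}
    for f in features:
        slot = by_image.setdefault(f.image_id, {})
        if f.image_kind in slot:
            raise ValueError(f"duplicate {f.image_kind!r} features for image {f.image_id!r}")
        slot[f.image_kind] = f

    if fusion_step is None:
        needed: Sequence[str] = (image_kind,)
    elif fusion_step == "textural":
        needed = ("glcm", "glrm")
    elif fusion_step == "full":
        needed = KIND_ORDER
    else:
        raise ValueError(f"unknown fusion_step {fusion_step!r}")

    rows, labels, index = [], [], []
    columns: list[str] | None = None
    for image_id in sorted(by_image):
        slot = by_image[image_id]
        missing = [k for k in needed if k not in slot]
        if missing:
            raise ValueError(f"image {image_id!r} is missing component vectors: {missing}")
        parts = [slot[k] for k in needed]
        rows.append(np.concatenate([p.values for p in parts]))
        labels.append(parts[0].label)
        index.append(image_id)
        if columns is None:
            columns = [
                f"{p.backbone_name}.{p.image_kind}.f{i + 1}"
                for p in parts
                for i in range(p.values.size)
            ]
    X = pd.DataFrame(rows, index=pd.Index(index, name="image_id"), columns=columns)
    y = pd.Series(labels, index=X.index, name="label")
    return X, y
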