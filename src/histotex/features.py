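"""Backbones with a 4-class output layer and last-FC-layer deep features.

A "deep feature" here is the pre-softmax activation vector of a network's
final fully connected layer — one value per class, so feature length equals
the number of classes (4 by default).  Downstream classical classifiers
consume these short vectors instead of raw pixels.

Two backbone families live in the registry:

* ``tiny_cnn`` — a desk-scale convolutional network implemented natively:
  a fixed, seeded three-block convolutional pyramid (conv 3x3 -> ReLU ->
  2x2 average pool) acts as the feature extractor, and a fully connected
  head (one hidden layer -> ``n_classes``-wide output layer) is trained
  with minibatch SGD + momentum on the cross-entropy loss.  ``pretrained``
  selects a canonical fixed filter bank shared across runs (transfer-style
  reuse); otherwise filters are drawn from the user seed.  Only the FC head
  is trained; the convolutional stage stays fixed.
* ``resnet101`` / ``inception`` / ``inception_resnet`` — the ImageNet
  transfer-learning architectures, available when the optional ``torch``
  extra is installed; their final classification layer is replaced with an
  ``n_classes``-wide fully connected layer.

Training honors the study's optimization settings (epochs, validation
frequency in iterations, mini-batch size, constant initial learning rate),
which are echoed into the training-log header.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.neural_network import MLPClassifier

from .datasets import LABELS, LabeledImage
from .preprocessing import BACKBONE_INPUTS, BackboneInputSpec

__all__ = [
    "TrainingConfig",
    "BackboneHandle",
    "DeepFeatureVector",
    "TrainingLog",
    "BACKBONE_REGISTRY",
    "build_backbone",
    "train_backbone",
    "extract_features",
    "fc_forward",
]

logger = logging.getLogger(__name__)

ImageKind = Literal["original", "glcm", "glrm"]

# canonical filter-bank seed used when pretrained=True, shared by all runs
_PRETRAINED_FILTER_SEED = 0x7E57ED

_TORCH_BACKBONES = ("resnet101", "inception", "inception_resnet")
BACKBONE_REGISTRY: tuple[str, ...] = ("tiny_cnn",) + _TORCH_BACKBONES


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults mirror the study's printed values
    (200 epochs, validation every 26 iterations, mini-batch 4, lr 0.0003)."""

    epochs: int = 200
    validation_frequency: int = 26
    mini_batch_size: int = 4
    initial_learning_rate: float = 3e-4
    momentum: float = 0.9
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if min(self.epochs, self.validation_frequency, self.mini_batch_size) < 1:
            raise ValueError("epochs, validation_frequency and mini_batch_size must be positive")
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be positive")


@dataclass
class DeepFeatureVector:
    """Last-FC-layer activations for one image, with provenance tags."""

    values: np.ndarray
    backbone_name: str
    image_kind: ImageKind
    image_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for image {self.image_id!r}")


@dataclass
class TrainingLog:
    """Header echoing the optimization settings plus per-validation entries."""

    header: dict
    entries: list[dict] = field(default_factory=list)
    first_epoch_train_accuracy: float = 0.0
    final_train_accuracy: float = 0.0


class _TinyConvNet:
    """Fixed seeded conv pyramid + trainable FC head (hidden 32 -> n_classes)."""

    channels = (8, 16, 32)
    hidden = 32

    def __init__(self, n_classes: int, filter_seed: int):
        self.n_classes = n_classes
        rng = np.random.default_rng(filter_seed)
        self.filters: list[np.ndarray] = []
        cin = 3
        for cout in self.channels:
            f = rng.standard_normal((cout, 3, 3, cin)) * np.sqrt(2.0 / (9 * cin))
            self.filters.append(f)
            cin = cout
        self.mlp: MLPClassifier | None = None
        self.feat_mean: np.ndarray | None = None
        self.feat_std: np.ndarray | None = None

    # -- fixed convolutional stage -------------------------------------
    @staticmethod
    def _conv_relu_pool(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
        win = sliding_window_view(x, (3, 3, x.shape[2]))[:, :, 0]
        h, w = win.shape[:2]
        out = win.reshape(h * w, -1) @ filters.reshape(filters.shape[0], -1).T
        out = np.maximum(out.reshape(h, w, -1), 0.0)
        h2, w2 = (h // 2) * 2, (w // 2) * 2
        return out[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2, -1).mean(axis=(1, 3))

    def conv_features(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(float) / 255.0
        x = (x - 0.5) / 0.25
        for f in self.filters:
            x = self._conv_relu_pool(x, f)
        h, w, c = x.shape
        hh, ww = (h // 2) * 2, (w // 2) * 2
        regions = x[:hh, :ww].reshape(2, hh // 2, 2, ww // 2, c).mean(axis=(1, 3)).ravel()
        return np.concatenate([regions, x.max(axis=(0, 1)), x.mean(axis=(0, 1))])

    def standardized(self, pixels: np.ndarray) -> np.ndarray:
        feats = self.conv_features(pixels)
        if self.feat_mean is not None:
            feats = (feats - self.feat_mean) / self.feat_std
        return feats

    def head_forward(self, pixels: np.ndarray) -> np.ndarray:
        feats = self.standardized(pixels)
        if self.mlp is not None:
            return fc_forward(self.mlp.coefs_, self.mlp.intercepts_, feats)
        # untrained handle: a deterministic seeded random head, so feature
        # extraction still works (callers are warned upstream)
        d = feats.size
        rng = np.random.default_rng(d)
        coefs = [
            rng.standard_normal((d, self.hidden)) * np.sqrt(2.0 / d),
            rng.standard_normal((self.hidden, self.n_classes)) * np.sqrt(2.0 / self.hidden),
        ]
        intercepts = [np.zeros(self.hidden), np.zeros(self.n_classes)]
        return fc_forward(coefs, intercepts, feats)

    def weight_checksum(self) -> int:
        crc = 0
        for f in self.filters:
            crc = zlib.crc32(np.ascontiguousarray(f).tobytes(), crc)
        if self.mlp is not None:
            for w in [*self.mlp.coefs_, *self.mlp.intercepts_]:
                crc = zlib.crc32(np.ascontiguousarray(w).tobytes(), crc)
        return crc


@dataclass
class BackboneHandle:
    """A backbone plus its class-width, input geometry and training state."""

    backbone_name: str
    n_classes: int
    pretrained: bool
    input_spec: BackboneInputSpec
    net: object = None
    classes: tuple[str, ...] = ()
    is_trained: bool = False
    post_softmax: bool = False  # expose post-softmax features instead of logits

    @property
    def final_layer_width(self) -> int:
        return self.n_classes

    def weight_checksum(self) -> int:
        return self.net.weight_checksum()


def fc_forward(coefs: Sequence[np.ndarray], intercepts: Sequence[np.ndarray], x: np.ndarray) -> np.ndarray:
    """Forward pass through fully connected layers with ReLU hidden units.

    Returns the *pre-softmax* activations of the last layer; for a single
    (W, b) pair this is exactly ``W.T @ x + b``.
    """
    a = np.asarray(x, dtype=float)
    for W, b in zip(coefs[:-1], intercepts[:-1]):
        a = np.maximum(a @ W + b, 0.0)
    return a @ coefs[-1] + intercepts[-1]


def build_backbone(
    name: str, n_classes: int = 4, pretrained: bool = True, seed: int = 0
) -> BackboneHandle:
    """Construct a registry backbone with an ``n_classes``-wide final FC layer.

    With ``pretrained=True`` the fixed layers come from shared canonical
    weights (ImageNet weights for the torch family, a canonical filter bank
    for ``tiny_cnn``); otherwise from a seeded random initialization.
    """
    if name not in BACKBONE_REGISTRY:
        raise KeyError(f"unknown backbone {name!r}; registry: {BACKBONE_REGISTRY}")
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    spec = BACKBONE_INPUTS[name]
    if name == "tiny_cnn":
        filter_seed = _PRETRAINED_FILTER_SEED if pretrained else seed
        net = _TinyConvNet(n_classes=n_classes, filter_seed=filter_seed)
    else:
        from . import _torch_backbones

        net = _torch_backbones.build(name, n_classes=n_classes, pretrained=pretrained, seed=seed)
    return BackboneHandle(
        backbone_name=name,
        n_classes=n_classes,
        pretrained=pretrained,
        input_spec=spec,
        net=net,
    )


def _check_images(handle: BackboneHandle, images: Sequence[LabeledImage]) -> None:
    h, w, _ = handle.input_spec.input_size
    for img in images:
        if img.pixels.shape != (h, w, 3):
            raise ValueError(
                f"image {img.image_id!r} has shape {img.pixels.shape}, "
                f"expected {(h, w, 3)} for backbone {handle.backbone_name!r}"
            )


def train_backbone(
    handle: BackboneHandle,
    train_images: Sequence[LabeledImage],
    val_images: Sequence[LabeledImage],
    cfg: TrainingConfig,
) -> tuple[BackboneHandle, TrainingLog]:
    """Fit the backbone's classification head with minibatch SGD + momentum.

    Cross-entropy on the class labels; the loss and held-out accuracy are
    logged every ``cfg.validation_frequency`` iterations (one iteration = one
    minibatch update).  Training is reproducible given the seed.
    """
    if not train_images:
        raise ValueError("training set is empty")
    classes = sorted({img.label for img in train_images})
    if len(classes) != handle.n_classes:
        missing = sorted(set(LABELS[: handle.n_classes]) - set(classes)) or classes
        raise ValueError(
            f"training set must contain all {handle.n_classes} classes; "
            f"observed {classes} (missing or extra: {missing})"
        )
    _check_images(handle, train_images)
    _check_images(handle, val_images)
    if handle.backbone_name != "tiny_cnn":
        from . import _torch_backbones

        return _torch_backbones.train(handle, train_images, val_images, cfg)

    net: _TinyConvNet = handle.net
    X = np.stack([net.conv_features(img.pixels) for img in train_images])
    y = np.array([img.label for img in train_images])
    net.feat_mean = X.mean(axis=0)
    net.feat_std = X.std(axis=0)
    net.feat_std[net.feat_std == 0] = 1.0
    Xs = (X - net.feat_mean) / net.feat_std
    if val_images:
        Xv = np.stack([net.standardized(img.pixels) for img in val_images])
        yv = np.array([img.label for img in val_images])
    else:
        Xv, yv = None, None

    net.mlp = MLPClassifier(
        hidden_layer_sizes=(net.hidden,),
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=cfg.initial_learning_rate,
        momentum=cfg.momentum,
        nesterovs_momentum=False,
        random_state=cfg.seed,
        max_iter=1,
    )
    log = TrainingLog(
        header={
            "backbone": handle.backbone_name,
            "epochs": cfg.epochs,
            "validation_frequency": cfg.validation_frequency,
            "mini_batch_size": cfg.mini_batch_size,
            "initial_learning_rate": cfg.initial_learning_rate,
            "n_train": len(train_images),
            "n_val": len(val_images),
        }
    )
    rng = np.random.default_rng(cfg.seed)
    classes_arr = np.array(classes)
    n = len(Xs)
    iteration = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.mini_batch_size):
            idx = order[start : start + cfg.mini_batch_size]
            net.mlp.partial_fit(Xs[idx], y[idx], classes=classes_arr)
            iteration += 1
            if iteration % cfg.validation_frequency == 0 and Xv is not None:
                log.entries.append(
                    {
                        "iteration": iteration,
                        "epoch": epoch,
                        "train_loss": float(net.mlp.loss_),
                        "val_accuracy": float((net.mlp.predict(Xv) == yv).mean()),
                    }
                )
        if epoch == 0:
            log.first_epoch_train_accuracy = float((net.mlp.predict(Xs) == y).mean())
    log.final_train_accuracy = float((net.mlp.predict(Xs) == y).mean())
    handle.classes = tuple(classes)
    handle.is_trained = True
    return handle, log


def extract_features(
    handle: BackboneHandle, image: LabeledImage, image_kind: ImageKind = "original"
) -> DeepFeatureVector:
    """Read the final-FC-layer activations for one image (evaluation mode).

    Returns pre-softmax activations by default (``handle.post_softmax``
    switches to softmax outputs).  Extraction is deterministic and never
    mutates the model.
    """
    if not handle.is_trained:
        logger.warning(
            "extracting features from untrained backbone %r", handle.backbone_name
        )
    _check_images(handle, [image])
    if handle.backbone_name != "tiny_cnn":
        from . import _torch_backbones

        values = _torch_backbones.forward_logits(handle, image)
    else:
        values = handle.net.head_forward(image.pixels)
    if handle.post_softmax:
        z = values - values.max()
        e = np.exp(z)
        values = e / e.sum()
    return DeepFeatureVector(
        values=values,
        backbone_name=handle.backbone_name,
        image_kind=image_kind,
        image_id=image.image_id,
        label=image.label,
    )
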