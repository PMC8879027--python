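"""Optional torch/torchvision adapter for the large transfer-learning backbones.

Everything here is imported lazily from :mod:`histotex.features`; the rest of
the package (and its test suite) runs without torch installed.  Install the
``histotex[deep]`` extra to enable resnet101 / inception / inception_resnet.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def _require_torch():
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - exercised only without torch
        raise ImportError(
            "backbone requires the optional 'deep' extra "
            "(pip install histotex[deep]); only the 'tiny_cnn' backbone is "
            "available without torch/torchvision"
        ) from exc
    return torch, torchvision


_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def build(name: str, n_classes: int, pretrained: bool, seed: int):
    """Build a torchvision backbone with its final FC layer replaced."""
    torch, torchvision = _require_torch()
    torch.manual_seed(seed)
    models = torchvision.models
    if name == "resnet101":
        net = models.resnet101(weights="IMAGENET1K_V1" if pretrained else None)
        net.fc = torch.nn.Linear(net.fc.in_features, n_classes)
    elif name == "inception":
        net = models.inception_v3(
            weights="IMAGENET1K_V1" if pretrained else None, aux_logits=True
        )
        net.fc = torch.nn.Linear(net.fc.in_features, n_classes)
    elif name == "inception_resnet":
        # torchvision has no InceptionResNet; inception_v3 with a resnet-style
        # trunk is not equivalent, so refuse rather than silently substitute
        raise ImportError(
            "inception_resnet requires a torchvision release providing it; "
            "use 'resnet101'/'inception' or the 'tiny_cnn' backbone"
        )
    else:  # pragma: no cover
        raise KeyError(name)
    net.eval()
    return net


def _to_tensor(torch, images: Sequence) -> "object":
    arr = np.stack([img.pixels for img in images]).astype(np.float32) / 255.0
    arr = (arr - _IMAGENET_MEAN) / _IMAGENET_STD
    return torch.from_numpy(arr.transpose(0, 3, 1, 2).astype(np.float32))


def train(handle, train_images, val_images, cfg):
    """Fine-tune all layers with SGD + momentum on cross-entropy."""
    from .features import TrainingLog

    torch, _ = _require_torch()
    net = handle.net
    classes = sorted({img.label for img in train_images})
    class_to_idx = {c: i for i, c in enumerate(classes)}
    X = _to_tensor(torch, train_images)
    y = torch.tensor([class_to_idx[img.label] for img in train_images])
    opt = torch.optim.SGD(
        net.parameters(), lr=cfg.initial_learning_rate, momentum=cfg.momentum
    )
    loss_fn = torch.nn.CrossEntropyLoss()
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
    g = torch.Generator().manual_seed(cfg.seed)
    net.train()
    iteration = 0
    for epoch in range(cfg.epochs):
        order = torch.randperm(len(train_images), generator=g)
        for start in range(0, len(train_images), cfg.mini_batch_size):
            idx = order[start : start + cfg.mini_batch_size]
            opt.zero_grad()
            out = net(X[idx])
            if isinstance(out, tuple):  # inception aux logits
                out = out[0]
            loss = loss_fn(out, y[idx])
            loss.backward()
            opt.step()
            iteration += 1
            if iteration % cfg.validation_frequency == 0 and val_images:
                log.entries.append(
                    {"iteration": iteration, "epoch": epoch, "train_loss": float(loss)}
                )
    net.eval()
    handle.classes = tuple(classes)
    handle.is_trained = True
    return handle, log


def forward_logits(handle, image) -> np.ndarray:
    torch, _ = _require_torch()
    net = handle.net
    net.eval()
    with torch.no_grad():
        out = net(_to_tensor(torch, [image]))
        if isinstance(out, tuple):
            out = out[0]
    return out.numpy()[0]
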