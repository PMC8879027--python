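"""End-to-end orchestration: preprocess -> texturize -> train -> extract ->
fuse -> classify -> report.

A run directory is self-describing: it holds the resolved configuration,
the (possibly synthetic) dataset, the textural images, the extracted deep
feature table, per-cell classification results and the comparison grid.
Each checkpointed stage records a hash of its resolved inputs, so re-running
a completed stage with unchanged inputs is a no-op and later stages can
resume from cached artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import __version__
from .classify import cross_validate
from .config import PipelineConfig
from .datasets import LabeledImage, SyntheticSpec, generate_dataset, read_dataset, write_dataset
from .features import DeepFeatureVector, build_backbone, extract_features, train_backbone
from .fusion import build_feature_table
from .metrics import (
    comparison_report,
    compute_metrics,
    confusion_matrix,
    macro_average,
    roc_auc,
)
from .preprocessing import BACKBONE_INPUTS, augment_dataset, resize_for_backbone
from .texture import texturize_image

__all__ = ["run_pipeline", "PipelineRun"]

logger = logging.getLogger(__name__)

IMAGE_KINDS = ("original", "glcm", "glrm")

#: feature-set name -> (fusion_step, image_kind) arguments for table building
FEATURE_SET_ARGS = {
    "original": (None, "original"),
    "glcm": (None, "glcm"),
    "glrm": (None, "glrm"),
    "glcm+glrm": ("textural", None),
    "full": ("full", None),
}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_fresh(marker: Path, input_hash: str) -> bool:
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("input_hash") == input_hash
    except (json.JSONDecodeError, OSError):
        return False


def _mark_stage(marker: Path, input_hash: str) -> None:
    marker.write_text(json.dumps({"input_hash": input_hash}))


class PipelineRun:
    """One pipeline execution bound to a run directory."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path | None = None):
        self.config = config
        self.run_dir = Path(out_dir if out_dir is not None else config.out_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.run_dir / "config.resolved.yaml")
        (self.run_dir / "run_info.json").write_text(
            json.dumps({"package_version": __version__, "seed": config.seed}, indent=2)
        )

    # -- stage 1: dataset ----------------------------------------------
    def stage_dataset(self) -> list[LabeledImage]:
        cfg = self.config
        ds = cfg.resolved_dataset()
        if isinstance(ds, str):
            logger.info("loading external dataset from %s", ds)
            return read_dataset(ds)
        marker = self.run_dir / "dataset" / ".stage.json"
        h = _hash(dataclasses.asdict(ds))
        if _stage_fresh(marker, h):
            logger.info("dataset stage cached; loading")
            return read_dataset(self.run_dir / "dataset" / "manifest.csv")
        images = generate_dataset(ds)
        write_dataset(images, self.run_dir / "dataset")
        _mark_stage(marker, h)
        return images

    # -- stages 2-4: preprocess, texturize, train, extract --------------
    def stage_features(self, images: list[LabeledImage]) -> pd.DataFrame:
        cfg = self.config
        feat_path = self.run_dir / "features" / "features.csv"
        marker = self.run_dir / "features" / ".stage.json"
        h = _hash(
            {
                "dataset": _hash([img.image_id for img in images]),
                "texture": dataclasses.asdict(cfg.texture),
                "backbones": list(cfg.backbones),
                "training": dataclasses.asdict(cfg.resolved_training()),
                "augmentation": dataclasses.asdict(cfg.augmentation),
                "val_fraction": cfg.val_fraction,
            }
        )
        if _stage_fresh(marker, h):
            logger.info("feature stage cached; loading %s", feat_path)
            return pd.read_csv(feat_path)
        feat_path.parent.mkdir(parents=True, exist_ok=True)

        rows = []
        tcfg = cfg.resolved_training()
        for backbone in cfg.backbones:
            spec = BACKBONE_INPUTS[backbone]
            h_in, w_in, _ = spec.input_size
            kind_images: dict[str, list[LabeledImage]] = {
                "original": [resize_for_backbone(img, spec) for img in images]
            }
            for method in ("glcm", "glrm"):
                tex_dir = self.run_dir / "textural" / backbone / method
                tex_dir.mkdir(parents=True, exist_ok=True)
                tex_images = [
                    texturize_image(
                        img,
                        method,
                        G=cfg.texture.G,
                        distance=cfg.texture.distance,
                        render_mode=cfg.texture.render_mode,
                        target_size=(h_in, w_in),
                        colormap=cfg.texture.colormap,
                        window=cfg.texture.window,
                        stride=cfg.texture.stride,
                    )
                    for img in images
                ]
                write_dataset(tex_images, tex_dir)
                kind_images[method] = tex_images

            for kind, kimgs in kind_images.items():
                labels = [img.label for img in kimgs]
                train_imgs, val_imgs = train_test_split(
                    kimgs,
                    test_size=cfg.val_fraction,
                    stratify=labels,
                    random_state=tcfg.seed,
                )
                if cfg.augmentation.n_augments_per_image > 0:
                    train_imgs = augment_dataset(train_imgs, cfg.augmentation)
                handle = build_backbone(backbone, n_classes=4, pretrained=True, seed=tcfg.seed)
                handle, log = train_backbone(handle, train_imgs, val_imgs, tcfg)
                (self.run_dir / "features" / f"train_log.{backbone}.{kind}.json").write_text(
                    json.dumps({"header": log.header, "entries": log.entries}, indent=2)
                )
                logger.info(
                    "%s/%s trained: final train accuracy %.3f",
                    backbone, kind, log.final_train_accuracy,
                )
                for img in kimgs:
                    f = extract_features(handle, img, image_kind=kind)
                    rows.append(
                        {
                            "image_id": f.image_id,
                            "label": f.label,
                            "backbone": backbone,
                            "image_kind": kind,
                            **{f"f{i + 1}": v for i, v in enumerate(f.values)},
                        }
                    )
        table = pd.DataFrame(rows).sort_values(["backbone", "image_kind", "image_id"])
        table.to_csv(feat_path, index=False)
        _mark_stage(marker, h)
        return table

    # -- stages 5-6: fuse + classify ------------------------------------
    def stage_classify(self, feat_table: pd.DataFrame) -> dict:
        cfg = self.config
        marker = self.run_dir / "reports" / ".stage.json"
        results_path = self.run_dir / "reports" / "results.json"
        h = _hash(
            {
                "features": _hash(np.round(feat_table.select_dtypes("number").to_numpy(), 12).tolist()),
                "classifiers": list(cfg.classifiers),
                "fusion_steps": list(cfg.fusion_steps),
                "cv": dataclasses.asdict(cfg.resolved_cv()),
            }
        )
        if _stage_fresh(marker, h):
            logger.info("classification stage cached; loading %s", results_path)
            return json.loads(results_path.read_text())
        results_path.parent.mkdir(parents=True, exist_ok=True)

        feature_sets = ["original", "glcm", "glrm"]
        if "textural" in cfg.fusion_steps:
            feature_sets.append("glcm+glrm")
        if "full" in cfg.fusion_steps:
            feature_sets.append("full")

        results: dict = {}
        protocol = cfg.resolved_cv()
        for backbone in cfg.backbones:
            sub = feat_table[feat_table["backbone"] == backbone]
            vectors = [
                DeepFeatureVector(
                    values=row[[c for c in sub.columns if c.startswith("f")]].to_numpy(dtype=float),
                    backbone_name=backbone,
                    image_kind=row["image_kind"],
                    image_id=row["image_id"],
                    label=row["label"],
                )
                for _, row in sub.iterrows()
            ]
            tables_dir = self.run_dir / "features"
            for fs in feature_sets:
                step, kind = FEATURE_SET_ARGS[fs]
                X, y = build_feature_table(vectors, fusion_step=step, image_kind=kind)
                X.join(y).to_csv(tables_dir / f"table.{backbone}.{fs.replace('+', '_')}.csv")
                for clf_kind in cfg.classifiers:
                    cv = cross_validate(cfg.classifier_spec(clf_kind), X, y, protocol=protocol)
                    classes = list(cv.confusion.index)
                    _, per_counts = confusion_matrix(cv.y_true, cv.y_pred, classes)
                    per_reports = {}
                    for c in classes:
                        rep = compute_metrics(per_counts[c])
                        if c in cv.scores.columns and cv.scores[c].notna().all():
                            rep.auc = roc_auc(cv.y_true, cv.scores[c], c).auc
                        per_reports[c] = rep
                    macro = macro_average(list(per_reports.values()), confusion=cv.confusion)
                    results.setdefault(backbone, {}).setdefault(fs, {})[clf_kind] = {
                        "overall_accuracy": macro.overall_accuracy,
                        "macro": macro.as_dict(),
                        "per_class": {c: r.as_dict() for c, r in per_reports.items()},
                        "confusion": cv.confusion.to_numpy().tolist(),
                        "classes": [str(c) for c in classes],
                    }
        results_path.write_text(json.dumps(results, indent=2, sort_keys=True))
        _mark_stage(marker, h)
        return results

    # -- stage 7: report -------------------------------------------------
    def stage_report(self, results: dict) -> pd.DataFrame:
        grid = {
            (backbone, fs, clf): {"overall_accuracy": cell["overall_accuracy"]}
            for backbone, by_fs in results.items()
            for fs, by_clf in by_fs.items()
            for clf, cell in by_clf.items()
        }
        present = [fs for fs in FEATURE_SET_ARGS if any(k[1] == fs for k in grid)]
        return comparison_report(
            grid,
            out_dir=self.run_dir / "reports",
            classifiers=list(self.config.classifiers),
            feature_sets=present,
        )

    def run(self) -> dict:
        images = self.stage_dataset()
        feat_table = self.stage_features(images)
        results = self.stage_classify(feat_table)
        self.stage_report(results)
        return results


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory with all artifacts."""
    run = PipelineRun(config, out_dir=out_dir)
    run.run()
    return run.run_dir
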