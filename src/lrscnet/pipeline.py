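"""End-to-end orchestration: split -> patches -> references -> encoder ->
semantic codes -> self-matching -> metrics.

Every stochastic stage carries its own explicit seed in
:class:`PipelineConfig`, so two runs with the same config and manifest
produce byte-identical evaluation reports.  Stage artifacts (the learned
references, the trained encoder, the report, a run log with every seed
and config value) are written to the output directory so any stage can
be re-run or audited in isolation; a load-and-evaluate pass over the
saved artifacts reproduces the train-and-evaluate report exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .encoder import (
    BackboneParams,
    SimilarityHeadParams,
    TrainConfig,
    load_encoder,
    save_encoder,
    train_encoder,
)
from .evaluation import auc, classification_metrics, confusion
from .exceptions import PipelineError, ValidationError
from .patches import (
    GrayImage,
    PatchConfig,
    extract_patches_cfg,
    load_image,
    read_manifest,
)
from .references import LocalReferenceSet, learn_local_references
from .semantic import image_semantic_code, self_match
from .synth import stratified_split

__all__ = [
    "ReferenceConfig",
    "SplitConfig",
    "PipelineConfig",
    "run_pipeline",
    "run_on_images",
    "predict_images",
    "evaluate_predictions",
]


@dataclass
class ReferenceConfig:
    """k benign / r malignant references plus the clustering seed and cap."""

    k: int = 10
    r: int = 10
    seed: int = 0
    max_iter: int = 300


@dataclass
class SplitConfig:
    train_fraction: float = 0.8
    seed: int = 0


@dataclass
class PipelineConfig:
    patch: PatchConfig = field(default_factory=PatchConfig)
    references: ReferenceConfig = field(default_factory=ReferenceConfig)
    encoder: TrainConfig = field(default_factory=TrainConfig)
    split: SplitConfig = field(default_factory=SplitConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"]["hidden_widths"] = list(self.encoder.hidden_widths)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        enc = dict(d.get("encoder", {}))
        if "hidden_widths" in enc:
            enc["hidden_widths"] = tuple(enc["hidden_widths"])
        return cls(
            patch=PatchConfig(**d.get("patch", {})),
            references=ReferenceConfig(**d.get("references", {})),
            encoder=TrainConfig(**enc),
            split=SplitConfig(**d.get("split", {})),
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _collect_patches(images: Sequence[GrayImage], cfg: PatchConfig):
    patches = []
    for img in images:
        patches.extend(extract_patches_cfg(img, cfg))
    return patches


def predict_images(
    images: Sequence[GrayImage],
    refs: LocalReferenceSet,
    bb: BackboneParams,
    head: SimilarityHeadParams,
    patch_cfg: PatchConfig,
) -> list[dict]:
    """Per-image prediction rows: id, truth (may be None), n bits, l,
    continuous score, predicted label, and the bit string."""
    rows = []
    for img in images:
        code = image_semantic_code(img, refs, bb, head, patch_cfg)
        decision = self_match(code)
        rows.append(
            {
                "image_id": img.image_id,
                "truth": img.label,
                "n": code.n,
                "l": decision.l,
                "score": float(code.per_patch_p.mean()),
                "predicted": decision.label,
                "bits": code.bit_string(),
            }
        )
    return rows


def evaluate_predictions(rows: Sequence[dict]) -> dict:
    """Confusion counts, the five headline metrics, and rank AUC from
    prediction rows that carry ground truth."""
    truth = [r["truth"] for r in rows]
    predicted = [r["predicted"] for r in rows]
    if any(t is None for t in truth):
        raise ValidationError("evaluation requires ground-truth labels on every image")
    counts = confusion(truth, predicted)
    metrics = classification_metrics(counts)
    classes = set(truth)
    auc_value: Optional[float] = None
    if len(classes) == 2:
        auc_value = auc([r["score"] for r in rows], truth)
    return {
        "counts": counts.as_dict(),
        "metrics": metrics,
        "auc": auc_value,
        "n_images": len(rows),
    }


def run_on_images(
    config: PipelineConfig,
    train_images: Sequence[GrayImage],
    test_images: Sequence[GrayImage],
) -> dict:
    """The full method on in-memory images; returns
    {report, refs, backbone, head, per_image, history}."""
    train_labels = {img.label for img in train_images}
    if train_labels != {"benign", "malignant"}:
        raise PipelineError(
            "split",
            f"training split must contain both classes, found {sorted(x for x in train_labels if x)}",
        )
    try:
        train_patches = _collect_patches(train_images, config.patch)
    except ValidationError as exc:
        raise PipelineError("patch-extraction", str(exc)) from exc
    if not train_patches:
        raise PipelineError("patch-extraction", "no training patches were extracted")
    try:
        refs = learn_local_references(
            train_patches,
            k=config.references.k,
            r=config.references.r,
            seed=config.references.seed,
            max_iter=config.references.max_iter,
        )
    except ValidationError as exc:
        raise PipelineError("reference-learning", str(exc)) from exc
    try:
        bb, head, history = train_encoder(train_patches, refs, config.encoder)
    except (ValidationError, RuntimeError) as exc:
        raise PipelineError("encoder-training", str(exc)) from exc
    try:
        per_image = predict_images(test_images, refs, bb, head, config.patch)
        report = evaluate_predictions(per_image)
    except ValidationError as exc:
        raise PipelineError("evaluation", str(exc)) from exc
    report["config_digest"] = config.digest()
    return {
        "report": report,
        "refs": refs,
        "backbone": bb,
        "head": head,
        "per_image": per_image,
        "history": history,
    }


def _load_split_images(manifest: Path | str, split_cfg: SplitConfig):
    rows = read_manifest(manifest)
    if not rows:
        raise PipelineError("manifest", f"manifest {manifest} has no rows")
    if any(r.split is None for r in rows):
        tags = stratified_split([r.label for r in rows], split_cfg.train_fraction, split_cfg.seed)
    else:
        tags = [r.split for r in rows]
    train, test = [], []
    for row, tag in zip(rows, tags):
        img = load_image(row.image, row.mask, row.label)
        (train if tag == "train" else test).append(img)
    return train, test


def run_pipeline(
    config: PipelineConfig,
    manifest: Path | str,
    out_dir: Path | str,
) -> dict:
    """Train and evaluate from a manifest; persist every artifact.

    Writes ``report.json`` (deterministic bytes), ``per_image.csv``,
    the references and encoder parameter files, and ``run_log.json``
    recording the full config, every seed, the clustering iteration
    count/objective and the per-epoch loss history.  Returns the report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_images, test_images = _load_split_images(manifest, config.split)
    result = run_on_images(config, train_images, test_images)

    result["refs"].save(out_dir)
    save_encoder(
        out_dir,
        result["backbone"],
        result["head"],
        meta={"m": config.patch.m, "k": config.references.k, "r": config.references.r,
              "config": config.to_dict(), "epoch_losses": result["history"]},
    )
    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(result["report"], indent=2, sort_keys=True) + "\n"
    )
    with open(out_dir / "per_image.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_id", "truth", "n", "l", "score", "predicted", "bits"]
        )
        writer.writeheader()
        writer.writerows(result["per_image"])
    log = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "manifest": str(manifest),
        "n_train": len(train_images),
        "n_test": len(test_images),
        "reference_learning": {
            key: result["refs"].meta.get(key)
            for key in ("seed", "iterations", "final_objective")
        },
        "epoch_losses": result["history"],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return result["report"]
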