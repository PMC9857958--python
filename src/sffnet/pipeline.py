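"""End-to-end run orchestration: synth -> preprocess -> augment -> train -> eval.

A :class:`RunConfig` (pydantic-validated, loadable from YAML) fixes every
stage's parameters and seeds; :func:`run_pipeline` executes the stages in
order and writes a JSON run record (resolved config, seeds, library
versions, stage timings, final metrics) plus metrics/history/ROC/confusion
files.  Two runs from the same config are bit-identical on the same
machine: every random draw is keyed by the config's seeds.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .augment import AugmentSpec, expand_dataset
from .model import SFFNet, SFFNetConfig, save_checkpoint
from .semi_sp import ROIPatch, apply_strategy
from .synthetic import CLASS_LABELS, PhantomSpec, iter_cohort, make_cohort
from .train_eval import (
    CLASS_ORDER,
    TrainConfig,
    evaluate,
    majority_vote_report,
    split_lesions,
    train,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "load_config",
    "benchmark_run_config",
]


class CohortConfig(BaseModel):
    n_lesions_per_class: int = 30
    slices_per_lesion: int | None = 4
    image_size: int = 256
    write_files: bool = False  # write cohort PNGs (slower; not needed to train)
    noise_sigma: float = 0.03
    hcc_edge_sigma: float = 0.8
    hcc_rim_contrast: float = 0.25
    hcc_irregularity: float = 0.10
    mficc_edge_sigma: float = 3.0
    mficc_rim_contrast: float = 0.0
    mficc_irregularity: float = 0.25

    def to_spec(self, seed: int) -> PhantomSpec:
        from .synthetic import LesionPhenotype

        return PhantomSpec(
            image_size=self.image_size,
            noise_sigma=self.noise_sigma,
            phenotypes={
                "HCC": LesionPhenotype(
                    self.hcc_edge_sigma, self.hcc_rim_contrast, self.hcc_irregularity
                ),
                "MF-ICC": LesionPhenotype(
                    self.mficc_edge_sigma, self.mficc_rim_contrast, self.mficc_irregularity
                ),
            },
            seed=seed,
        )


class PreprocessConfig(BaseModel):
    strategy: Literal["semi_sp", "double", "triple", "whole_image", "lesion_only"] = "semi_sp"
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)


class AugmentConfig(BaseModel):
    copies_per_image: int = 0
    max_translation: float = 0.1
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: float = 15.0
    augment_test_set: bool = False  # refused; exists so the guard is testable

    def to_spec(self, seed: int) -> AugmentSpec:
        return AugmentSpec(
            max_translation=self.max_translation,
            scale_range=self.scale_range,
            rotation_range_deg=self.rotation_range_deg,
            copies_per_image=self.copies_per_image,
            seed=seed,
        )


class ModelConfig(BaseModel):
    preset: Literal["full", "reduced"] = "reduced"
    input_size: int = 224
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def to_config(self, seed: int) -> SFFNetConfig:
        return SFFNetConfig.preset(
            self.preset,
            input_size=self.input_size,
            cbam_reduction=self.cbam_reduction,
            cbam_spatial_kernel=self.cbam_spatial_kernel,
            input_channels=1,
            init_seed=seed,
        )


class TrainingConfig(BaseModel):
    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_step_epochs: int = 30
    batch_size: int = 16
    epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.0

    def to_config(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    augment: AugmentConfig = Field(default_factory=AugmentConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        if self.augment.augment_test_set:
            raise ValueError(
                "config error: augmentation of the test set is not permitted; "
                "the held-out set must remain unmodified"
            )
        return self


def load_config(path: str | Path) -> RunConfig:
    return RunConfig(**yaml.safe_load(Path(path).read_text()))


def benchmark_run_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """The package's reference synthetic benchmark configuration.

    A CPU-scale end-to-end run: 30 lesions per class with 4 slices each,
    Semi-SP preprocessing, the reduced-depth model at 64x64 input, and a
    25-epoch momentum-SGD schedule (lr 0.01, x0.1 every 10 epochs).  The
    resolution, depth and epoch count are sized for a single CPU core; the
    two phenotypes remain cleanly separable at this scale, so the run
    validates the full training/evaluation loop and the learnability of
    the edge-phenotype signal.
    """
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        cohort=CohortConfig(n_lesions_per_class=30, slices_per_lesion=4),
        preprocess=PreprocessConfig(strategy="semi_sp"),
        model=ModelConfig(preset="reduced", input_size=64),
        training=TrainingConfig(
            initial_lr=0.01,
            lr_decay_factor=0.1,
            lr_step_epochs=10,
            batch_size=16,
            epochs=25,
        ),
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _patch_to_record(patch: ROIPatch) -> dict:
    p = patch.provenance
    return {
        "lesion_id": p.get("lesion_id"),
        "class_label": p.get("class_label"),
        "slice_index": p.get("slice_index"),
        "split": p.get("split"),
        "augmented": bool(p.get("augmented", False)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the run record (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record: dict = {
        "config": json.loads(config.model_dump_json()),
        "versions": {
            "sffnet": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "stages": {},
        "outputs": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Timer()

    # -- synth ------------------------------------------------------------
    with stage("synth"):
        spec = config.cohort.to_spec(config.seed)
        if config.cohort.write_files:
            manifest = make_cohort(
                config.cohort.n_lesions_per_class,
                spec,
                config.seed,
                out / "cohort",
                config.cohort.slices_per_lesion,
            )
            record["outputs"]["cohort_manifest"] = str(out / "cohort" / "manifest.csv")
        slices = list(
            iter_cohort(
                config.cohort.n_lesions_per_class,
                spec,
                config.seed,
                config.cohort.slices_per_lesion,
            )
        )
        record["stages"]["synth"] = {
            "n_slices": len(slices),
            "n_lesions": len({sl.lesion_id for sl, _ in slices}),
        }

    # -- split ------------------------------------------------------------
    with stage("split"):
        lesion_table = {sl.lesion_id: sl.class_label for sl, _ in slices}
        assignment = split_lesions(lesion_table, config.split_ratios, config.seed)
        splits_of = assignment.assignment
        per_split = {
            s: sum(1 for v in splits_of.values() if v == s)
            for s in ("train", "validation", "test")
        }
        record["stages"]["split"] = {"lesions_per_split": per_split}

    # -- preprocess -------------------------------------------------------
    with stage("preprocess"):
        patches: list[ROIPatch] = []
        for sl, mask in slices:
            patch = apply_strategy(
                sl,
                mask,
                config.preprocess.strategy,
                out_size=config.model.input_size,
                clip_limit=config.preprocess.clip_limit,
                tile_grid=tuple(config.preprocess.tile_grid),
            )
            patch.provenance["split"] = splits_of[sl.lesion_id]
            patches.append(patch)
        record["stages"]["preprocess"] = {
            "strategy": config.preprocess.strategy,
            "n_patches": len(patches),
        }

    # -- augment ----------------------------------------------------------
    with stage("augment"):
        train_val = [p for p in patches if p.provenance["split"] != "test"]
        test_patches = [p for p in patches if p.provenance["split"] == "test"]
        if config.augment.copies_per_image > 0:
            aug_spec = config.augment.to_spec(config.seed)
            train_val = expand_dataset(train_val, aug_spec)
        record["stages"]["augment"] = {
            "copies_per_image": config.augment.copies_per_image,
            "n_train_val": len(train_val),
            "n_test": len(test_patches),
        }

    # -- train ------------------------------------------------------------
    with stage("train"):
        label_index = {c: i for i, c in enumerate(CLASS_ORDER)}

        def pack(items: list[ROIPatch]) -> tuple[np.ndarray, np.ndarray]:
            x = np.stack([p.pixels for p in items])[:, None, :, :]
            y = np.array([label_index[p.provenance["class_label"]] for p in items])
            return x.astype(np.float32), y

        datasets = {
            "train": pack([p for p in train_val if p.provenance["split"] == "train"]),
            "validation": pack(
                [p for p in train_val if p.provenance["split"] == "validation"]
            ),
        }
        model = SFFNet(config.model.to_config(config.seed))
        result = train(model, datasets, config.training.to_config(config.seed))
        result.history.to_csv(out / "history.csv", index=False)
        save_checkpoint(model, out / "checkpoint.npz")
        record["outputs"]["history"] = str(out / "history.csv")
        record["outputs"]["checkpoint"] = str(out / "checkpoint.npz")
        record["stages"]["train"] = {
            "best_epoch": result.best_epoch,
            "best_val_accuracy": result.best_val_accuracy,
            "n_parameters": model.num_parameters(),
        }

    # -- eval -------------------------------------------------------------
    with stage("eval"):
        x_test, y_test = pack(test_patches)
        report = evaluate(model, x_test, y_test)
        probs = model.predict_proba(x_test)
        preds = probs.argmax(axis=1)
        lesions = [p.provenance["lesion_id"] for p in test_patches]
        lesion_report = majority_vote_report(y_test, preds, lesions)

        from .train_eval import POSITIVE_CLASS, roc_auc

        pos = CLASS_ORDER.index(POSITIVE_CLASS)
        fpr, tpr, _ = roc_auc(probs[:, pos], (y_test == pos).astype(int))
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / "roc.csv", index=False)
        pd.DataFrame(
            report.confusion,
            index=list(CLASS_ORDER),
            columns=list(CLASS_ORDER),
        ).to_csv(out / "confusion.csv")
        metrics = {
            "per_slice": report.to_dict(),
            "per_lesion_majority_vote": lesion_report.to_dict(),
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        record["outputs"]["metrics"] = str(out / "metrics.json")
        record["outputs"]["roc"] = str(out / "roc.csv")
        record["outputs"]["confusion"] = str(out / "confusion.csv")
        record["stages"]["eval"] = {
            "test_accuracy": report.accuracy,
            "test_macro_auc": report.macro_auc,
        }

    record["timings_sec"] = timings
    record["metrics"] = metrics
    (out / "run_record.json").write_text(json.dumps(record, indent=1))
    record["outputs"]["run_record"] = str(out / "run_record.json")
    return record
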