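"""End-to-end pipeline: generate -> preprocess -> segment -> augment ->
split -> train (or grid search) -> evaluate -> select.

Every stage persists its artifacts under the run directory (manifests,
rejection log, lineage, per-run histories, evaluation reports, the
selection verdict and a machine-readable summary), and the whole run is
reproducible from (config, master seed).

Larva-present captures pass through the quality filter that models the
raw-to-segmented attrition of a curated image set; larva-absent captures
are cropped unconditionally (threshold 0) at their G-maximum, which is
exactly the frame a deployed detector would hand the classifier when no
larva is in view.  That is how the binary classification task acquires its
negative class.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import AugmentationPolicy, augment_dataset, write_lineage
from .classifier import (
    CNNArchitectureSpec,
    TrainingConfig,
    build_cnn,
    grid_search,
    save_grid_results,
    split_dataset,
    train,
)
from .dataset import LabeledDataset
from .evaluate import evaluate_model, select_optimal
from .exceptions import PipelineError
from .preprocess import select_band
from .segment import segment_dataset, write_rejection_log
from .synthetic import generate_dataset, write_manifest

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML (schema v1)."""

    schema_version: int = 1
    # synthetic captures
    n_present: int = 100
    n_absent: int = 100
    species: str = "chironomid"
    image_side: int = 1200
    noise_sd: float = 5.0
    background_level: float = 30.0
    # preprocessing
    wavelet_family: str = "haar"
    wavelet_level: int = 1
    band_selection_captures: int = 10
    # segmentation
    quality_threshold: float = 50.0
    crop_size: int = 300
    # augmentation
    augment_factor: int = 4
    rotation_range: float = 30.0
    shift_range: float = 0.10
    zoom_range: float = 0.20
    horizontal_flip: bool = True
    # split / training
    split_ratio: float = 0.7
    lineage_aware_split: bool = False
    dense_units: int = 256
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    # grid search
    run_grid: bool = False
    epochs_grid: tuple[int, ...] = (200, 300)
    lr_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
    # selection
    accuracy_floor: float = 1.0
    # artifact verbosity
    save_images: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["epochs_grid"] = list(self.epochs_grid)
        d["lr_grid"] = list(self.lr_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("schema_version", 1) != 1:
            raise PipelineError("config", f"unsupported schema_version {d['schema_version']}")
        for k in ("epochs_grid", "lr_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int = 0) -> Path:
    """Execute the full workflow; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts of completed stages remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": seed, "package_version": __version__}

    # -- generate ---------------------------------------------------------
    try:
        present = generate_dataset(
            config.n_present, 0, config.species, seed=seed,
            image_side=config.image_side, noise_sd=config.noise_sd,
            background_level=config.background_level,
        )
        absent = generate_dataset(
            0, config.n_absent, config.species, seed=seed + 1,
            image_side=config.image_side, noise_sd=config.noise_sd,
            background_level=config.background_level,
        )
        write_manifest(present + absent, out / "captures_manifest.csv")
        if config.save_images:
            from .synthetic import save_capture

            capdir = out / "captures"
            for cap in present + absent:
                save_capture(cap, capdir)
        summary["n_captures"] = len(present) + len(absent)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("generate", str(e)) from e

    # -- band selection ---------------------------------------------------
    try:
        probe = present[: config.band_selection_captures] or absent[: config.band_selection_captures]
        band = select_band(probe, config.wavelet_family, config.wavelet_level)
        summary["selected_band"] = band
        (out / "band_selection.json").write_text(json.dumps({"selected_band": band}))
    except Exception as e:
        raise PipelineError("preprocess", str(e)) from e

    # -- segment ----------------------------------------------------------
    try:
        kw = dict(
            size=config.crop_size,
            family=config.wavelet_family,
            level=config.wavelet_level,
            band=band,
        )
        pos_samples, pos_log = segment_dataset(present, config.quality_threshold, **kw)
        neg_samples, neg_log = segment_dataset(absent, 0.0, **kw)
        write_rejection_log(pos_log + neg_log, out / "segmentation_log.csv")
        if not pos_samples:
            raise PipelineError(
                "segment", "no samples survived the quality filter"
            )
        summary["n_segmented"] = {"present": len(pos_samples), "absent": len(neg_samples)}
        if config.save_images:
            from .segment import save_samples

            save_samples(pos_samples + neg_samples, out / "segmented")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("segment", str(e)) from e

    # -- augment ----------------------------------------------------------
    try:
        policy = AugmentationPolicy(
            rotation_range=config.rotation_range,
            shift_range=config.shift_range,
            horizontal_flip=config.horizontal_flip,
            zoom_range=config.zoom_range,
            factor=config.augment_factor,
            seed=seed + 2,
        )
        augmented = augment_dataset(pos_samples + neg_samples, policy)
        write_lineage(augmented, out / "augmentation_lineage.csv")
        dataset = LabeledDataset(augmented)
        summary["n_augmented"] = len(augmented)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("augment", str(e)) from e

    # -- split ------------------------------------------------------------
    try:
        train_ds, test_ds = split_dataset(
            dataset,
            ratio=config.split_ratio,
            seed=seed + 3,
            stratified=True,
            lineage_aware=config.lineage_aware_split,
        )
        summary["split"] = {
            "train": len(train_ds),
            "test": len(test_ds),
            "train_classes": {str(k): v for k, v in train_ds.class_counts().items()},
            "test_classes": {str(k): v for k, v in test_ds.class_counts().items()},
        }
        (out / "splits.json").write_text(
            json.dumps(
                {
                    "train": [s.sample_id for s in train_ds.samples],
                    "test": [s.sample_id for s in test_ds.samples],
                },
                indent=1,
            )
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("split", str(e)) from e

    # -- train / grid -----------------------------------------------------
    try:
        spec = CNNArchitectureSpec(input_side=config.crop_size, dense_units=config.dense_units)
        base_cfg = TrainingConfig(
            batch_size=config.batch_size,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            optimizer=config.optimizer,
            split_ratio=config.split_ratio,
            seed=seed + 4,
        )
        traindir = out / "training"
        traindir.mkdir(exist_ok=True)
        if config.run_grid:
            results = grid_search(
                train_ds,
                test_ds,
                epochs_grid=config.epochs_grid,
                lr_grid=config.lr_grid,
                config=base_cfg,
                model_builder=lambda s: build_cnn(spec, seed=s),
            )
            save_grid_results(results, traindir)
            best = results[0]
            winner_cfg = TrainingConfig(
                batch_size=config.batch_size,
                epochs=best.epochs,
                learning_rate=best.learning_rate,
                optimizer=config.optimizer,
                split_ratio=config.split_ratio,
                seed=base_cfg.seed,
            )
            model = build_cnn(spec, seed=base_cfg.seed)
            trained = train(model, train_ds, winner_cfg, test_ds)
        else:
            model = build_cnn(spec, seed=base_cfg.seed)
            trained = train(model, train_ds, base_cfg, test_ds)
        trained.save_history(traindir / "history.csv")
        summary["training"] = {
            "epochs": trained.config.epochs,
            "learning_rate": trained.config.learning_rate,
            "training_seconds": trained.training_seconds,
            "diverged": trained.diverged,
            "final_val_acc": trained.final_val_accuracy,
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("train", str(e)) from e

    # -- evaluate & select ------------------------------------------------
    try:
        Xt, yt = test_ds.to_arrays()
        report = evaluate_model(
            trained.model, Xt, yt, model_id="cnn", training_seconds=trained.training_seconds
        )
        (out / "evaluation.json").write_text(report.to_json())
        verdict = select_optimal([report], accuracy_floor=config.accuracy_floor)
        (out / "selection.json").write_text(verdict.to_json())
        summary["evaluation"] = {
            "accuracy": report.accuracy,
            "f1": report.f1,
            "rmse": report.rmse,
        }
        summary["selected_model"] = verdict.selected.model_id
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("evaluate", str(e)) from e

    summary["python"] = platform.python_version()
    summary["numpy"] = np.__version__
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
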