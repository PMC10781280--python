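"""The compact larva CNN: architecture, splitting, training, grid search.

The classifier is a 10-layer network for 300x300 3-channel crops: three
blocks of unpadded 3x3 convolution (16, 32, 64 filters, ReLU) each
followed by 2x2 max-pooling, then Flatten, Dense(256 or 512, ReLU),
Dropout(0.5) and a single sigmoid unit.  With no padding each convolution
shrinks the side by 2 and each pool halves it (floor), so a 300-px input
traces 298, 149, 147, 73, 71, 35 and flattens to 35*35*64 = 78,400.

``compute_layer_shapes`` derives that chain analytically, without the
learning backend; ``build_cnn`` constructs the trainable model, whose
backend-reported shapes must agree.  ``grid_search`` runs the epochs x
learning-rate protocol (2 x 4 = 8 combinations at full scale) and ranks
runs by validation accuracy, then validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .exceptions import ConfigurationError, UsageError
from .nn import Conv2D, Dense, Dropout, Flatten, Sequential

__all__ = [
    "CNNArchitectureSpec",
    "TrainingConfig",
    "TrainedModel",
    "GridRunResult",
    "compute_layer_shapes",
    "build_cnn",
    "split_dataset",
    "split_indices",
    "train",
    "grid_search",
    "training_unstable",
]

CONV_FILTERS = (16, 32, 64)


@dataclass(frozen=True)
class CNNArchitectureSpec:
    """Architecture of the 10-layer larva CNN.

    The three conv blocks are fixed at 16/32/64 3x3 filters with ReLU and
    2x2 pooling; only the input side, the dense width (256 or 512) and the
    channel count are knobs.
    """

    input_side: int = 300
    channels: int = 3
    dense_units: int = 256
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.dense_units not in (256, 512):
            raise ConfigurationError("dense_units must be 256 or 512")
        if self.input_side < 1 or self.channels < 1:
            raise ConfigurationError("input_side and channels must be positive")


@dataclass
class TrainingConfig:
    """Training protocol defaults: Adam, batch 32, 7:3 split."""

    batch_size: int = 32
    epochs: int = 300
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    split_ratio: float = 0.7
    seed: int = 0


@dataclass
class TrainedModel:
    model: Sequential
    history: pd.DataFrame
    training_seconds: float
    config: TrainingConfig
    diverged: bool = False
    architecture: CNNArchitectureSpec | None = None

    @property
    def final_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[-1])

    @property
    def final_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[-1])

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def compute_layer_shapes(spec: CNNArchitectureSpec) -> list[tuple[str, tuple]]:
    """Analytic shape chain for the 10 layer rows; no backend involved.

    Unpadded 3x3 convolution: side -> side - 2; 2x2 pooling:
    side -> floor(side / 2); flatten length = final_side**2 * 64.
    """
    side = spec.input_side
    rows: list[tuple[str, tuple]] = []
    for f in CONV_FILTERS:
        side = side - 2
        if side < 1:
            raise ConfigurationError(
                f"input side {spec.input_side} exhausts the conv/pool chain"
            )
        rows.append(("Conv2D", (side, side, f)))
        side = side // 2
        if side < 1:
            raise ConfigurationError(
                f"input side {spec.input_side} exhausts the conv/pool chain"
            )
        rows.append(("MaxPooling", (side, side, f)))
    rows.append(("Flatten", (side * side * CONV_FILTERS[-1],)))
    rows.append(("Dense", (spec.dense_units,)))
    rows.append(("Dropout", (spec.dense_units,)))
    rows.append(("Dense", (1,)))
    return rows


def flatten_length(spec: CNNArchitectureSpec) -> int:
    return compute_layer_shapes(spec)[6][1][0]


def build_cnn(spec: CNNArchitectureSpec | None = None, seed: int = 0) -> Sequential:
    """Construct the trainable 10-layer binary classifier."""
    spec = spec or CNNArchitectureSpec()
    compute_layer_shapes(spec)  # validates the chain before building
    model = Sequential(
        [
            Conv2D(16, activation="relu", pool=2),
            Conv2D(32, activation="relu", pool=2),
            Conv2D(64, activation="relu", pool=2),
            Flatten(),
            Dense(spec.dense_units, activation="relu"),
            Dropout(spec.dropout_rate),
            Dense(1, activation="sigmoid"),
        ]
    )
    model.build((spec.input_side, spec.input_side, spec.channels), seed=seed)
    return model


# -- splitting -------------------------------------------------------------


def split_indices(
    labels: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic disjoint, exhaustive train/test index partition.

    The train side receives exactly ``floor(ratio * n)`` indices.  Under
    stratification each class contributes ``floor(ratio * n_c)`` and the
    remainder is topped up by largest fractional remainder, so per-class
    skew is at most 1.  With ``groups`` (lineage-aware mode) whole groups
    are assigned greedily to the train side until its quota is reached,
    keeping augmentation siblings on one side; exact sizes then depend on
    group sizes.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0 or not 0.0 < ratio < 1.0:
        raise UsageError("need a non-empty dataset and 0 < ratio < 1")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(ratio * n))

    if groups is not None:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        train_mask = np.zeros(n, dtype=bool)
        taken = 0
        for gkey in uniq:
            if taken >= n_train:
                break
            m = groups == gkey
            train_mask |= m
            taken += int(m.sum())
        return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)

    if not stratified:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise UsageError("stratified split needs at least 2 samples per class")
    base = np.floor(ratio * counts).astype(int)
    rem = ratio * counts - base
    shortfall = n_train - base.sum()
    for ci in np.argsort(-rem)[: max(shortfall, 0)]:
        base[ci] += 1
    train_idx = []
    for cls, take in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(members))
        train_idx.append(members[perm[:take]])
    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    return train, np.flatnonzero(~mask)


def split_dataset(
    dataset: LabeledDataset,
    ratio: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
    lineage_aware: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a dataset 7:3 (by default); see :func:`split_indices`."""
    groups = dataset.lineage_groups() if lineage_aware else None
    tr, te = split_indices(dataset.labels, ratio, seed, stratified, groups)
    return dataset.subset(tr, split="train"), dataset.subset(te, split="test")


# -- training --------------------------------------------------------------


def _to_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, LabeledDataset):
        return data.to_arrays()
    X, y = data
    return np.asarray(X), np.asarray(y)


def train(
    model: Sequential,
    train_data,
    config: TrainingConfig,
    validation_data=None,
) -> TrainedModel:
    """Train ``model`` under the protocol in ``config``.

    Images are scaled from 8-bit intensities to [0, 1].  Divergence to a
    non-finite loss stops the run and sets ``diverged`` instead of raising,
    so a grid search survives unstable configurations.
    """
    X, y = _to_arrays(train_data)
    X = np.asarray(X, np.float32) / 255.0 if X.dtype == np.uint8 else np.asarray(X, np.float32)
    val = None
    if validation_data is not None:
        Xv, yv = _to_arrays(validation_data)
        Xv = np.asarray(Xv, np.float32) / 255.0 if Xv.dtype == np.uint8 else np.asarray(Xv, np.float32)
        val = (Xv, yv)
    hist = model.fit(
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        optimizer=config.optimizer,
        lr=config.learning_rate,
        seed=config.seed,
        validation_data=val,
    )
    seconds = hist.pop("training_seconds")
    diverged = hist.pop("diverged")
    return TrainedModel(
        model=model,
        history=pd.DataFrame(hist),
        training_seconds=seconds,
        config=config,
        diverged=diverged,
    )


def training_unstable(history: pd.DataFrame, rise_tolerance: float = 0.10) -> bool:
    """Heuristic instability flag: divergence, a loss spike, or
    oscillation that never settles.

    True when the loss is ever non-finite; when the loss later exceeds its
    starting value by more than ``rise_tolerance``; or when the minimum is
    reached well before the end (first three quarters) yet the final
    quarter still averages more than ``(1 + rise_tolerance)`` times that
    minimum — the signature of a step size too large to converge.
    """
    loss = np.asarray(history["train_loss"], dtype=float)
    if not np.all(np.isfinite(loss)):
        return True
    n = len(loss)
    if n < 2:
        return False
    if np.max(loss[1:]) > loss[0] * (1.0 + rise_tolerance):
        return True
    best = int(np.argmin(loss))
    tail = loss[-max(n // 4, 1):]
    return bool(best < 3 * n // 4 and tail.mean() > loss[best] * (1.0 + rise_tolerance))


# -- grid search -----------------------------------------------------------


@dataclass
class GridRunResult:
    epochs: int
    learning_rate: float
    val_acc: float
    val_loss: float
    training_seconds: float
    diverged: bool
    history: pd.DataFrame = field(repr=False)
    rank: int = -1

    def summary(self) -> dict:
        return {
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "val_acc": None if np.isnan(self.val_acc) else self.val_acc,
            "val_loss": None if np.isnan(self.val_loss) else self.val_loss,
            "training_seconds": self.training_seconds,
            "diverged": self.diverged,
            "rank": self.rank,
        }


def grid_search(
    train_data,
    validation_data,
    epochs_grid: tuple[int, ...] = (200, 300),
    lr_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2),
    config: TrainingConfig | None = None,
    model_builder=None,
) -> list[GridRunResult]:
    """Run every (epochs, lr) combination and rank the models.

    The split is fixed by the caller; every run trains a freshly seeded
    model.  Ranking: validation accuracy descending, ties broken by
    validation loss ascending; diverged runs sort last.  Returns results
    in rank order with per-run history attached.
    """
    config = config or TrainingConfig()
    if model_builder is None:
        model_builder = lambda seed: build_cnn(CNNArchitectureSpec(), seed=seed)
    results = []
    for i, epochs in enumerate(epochs_grid):
        for j, lr in enumerate(lr_grid):
            run_seed = config.seed + 1000 * i + j
            model = model_builder(run_seed)
            run_cfg = TrainingConfig(
                batch_size=config.batch_size,
                epochs=epochs,
                learning_rate=lr,
                optimizer=config.optimizer,
                split_ratio=config.split_ratio,
                seed=run_seed,
            )
            tm = train(model, train_data, run_cfg, validation_data)
            results.append(
                GridRunResult(
                    epochs=epochs,
                    learning_rate=lr,
                    val_acc=tm.final_val_accuracy,
                    val_loss=tm.final_val_loss,
                    training_seconds=tm.training_seconds,
                    diverged=tm.diverged,
                    history=tm.history,
                )
            )

    def key(r: GridRunResult):
        bad = r.diverged or not np.isfinite(r.val_acc)
        return (bad, -(r.val_acc if not bad else 0.0), r.val_loss if not bad else np.inf)

    results.sort(key=key)
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def save_grid_results(results: list[GridRunResult], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "grid_results.json").write_text(
        json.dumps([r.summary() for r in results], indent=1)
    )
    for r in results:
        r.history.to_csv(outdir / f"history_e{r.epochs}_lr{r.learning_rate:g}.csv", index=False)
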