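"""Ordered labeled sample collection with split and lineage bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UsageError
from .segment import SegmentedSample

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """An ordered list of segmented (possibly augmented) samples.

    ``split`` marks which partition the dataset represents ("" when
    unsplit).  Lineage groups tie augmented variants to their original so a
    lineage-aware split can keep siblings on one side.
    """

    samples: list[SegmentedSample]
    split: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def lineage_groups(self) -> np.ndarray:
        """Group key per sample: its own id for originals, else the parent's."""
        return np.array([s.parent_id or s.sample_id for s in self.samples])

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, indices: np.ndarray, split: str = "") -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices], split=split)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): X as (n, S, S, 3) uint8 stack, y as int labels."""
        if not self.samples:
            raise UsageError("dataset is empty")
        X = np.stack([s.grid for s in self.samples])
        return X, self.labels
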