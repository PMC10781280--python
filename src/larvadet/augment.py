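"""Seeded geometric augmentation of segmented crops.

The segmented dataset is expanded by an integer factor (default 4, with
the originals counted as one of the four): each original contributes
``factor - 1`` variants produced by a random horizontal flip, rotation,
shift and zoom.  Transform parameters for a variant are drawn from a
dedicated ``draw_seed`` derived from the policy seed with the same mixing
rule the capture generator uses, and are recorded per variant, so every
variant is regenerable bit-exactly from its lineage.

Pixels exposed by rotation, shift or zoom-out are filled by nearest-edge
replication.  Labels, species and geometry (300x300) are preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from .exceptions import UsageError
from .segment import SegmentedSample
from .synthetic import derive_child_seed

__all__ = ["AugmentationPolicy", "augment_image", "augment_dataset", "write_lineage"]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ranges for the random geometric transforms.

    rotation_range: max |rotation| in degrees.
    shift_range: max |shift| per axis, as a fraction of the image side.
    zoom_range: max |zoom - 1|; zoom is drawn in [1 - z, 1 + z].
    horizontal_flip: whether to flip with probability 0.5.
    factor: total expansion factor (originals included).
    """

    rotation_range: float = 30.0
    shift_range: float = 0.10
    horizontal_flip: bool = True
    zoom_range: float = 0.20
    factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise UsageError("factor must be >= 1")
        if min(self.rotation_range, self.shift_range, self.zoom_range) < 0:
            raise UsageError("transform ranges must be non-negative")


def _draw_params(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    # Draw order is fixed (flip, rotation, shifts, zoom) for reproducibility.
    return {
        "flip": bool(policy.horizontal_flip and rng.random() < 0.5),
        "rotation_deg": float(rng.uniform(-policy.rotation_range, policy.rotation_range)),
        "shift_rows": float(rng.uniform(-policy.shift_range, policy.shift_range)),
        "shift_cols": float(rng.uniform(-policy.shift_range, policy.shift_range)),
        "zoom": float(rng.uniform(1.0 - policy.zoom_range, 1.0 + policy.zoom_range)),
    }


def _apply_params(grid: np.ndarray, params: dict) -> np.ndarray:
    out = grid
    if params["flip"]:
        out = out[:, ::-1]
    side = out.shape[0]
    identity = (
        params["rotation_deg"] == 0.0
        and params["shift_rows"] == 0.0
        and params["shift_cols"] == 0.0
        and params["zoom"] == 1.0
    )
    if identity:
        return np.ascontiguousarray(out)
    c = (side - 1) / 2.0
    # rotate and zoom about the image center, then shift
    recenter = AffineTransform(translation=(-c, -c))
    rotzoom = AffineTransform(rotation=np.deg2rad(params["rotation_deg"]), scale=params["zoom"])
    back = AffineTransform(
        translation=(
            c + params["shift_cols"] * side,
            c + params["shift_rows"] * side,
        )
    )
    tform = recenter + rotzoom + back
    warped = warp(
        out.astype(np.float32),
        tform.inverse,
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return np.clip(np.rint(warped), 0, 255).astype(np.uint8)


def augment_image(
    sample: SegmentedSample, policy: AugmentationPolicy, draw_seed: int
) -> SegmentedSample:
    """One augmented variant of ``sample``, deterministic in ``draw_seed``."""
    rng = np.random.default_rng(int(draw_seed))
    params = _draw_params(policy, rng)
    grid = _apply_params(sample.grid, params)
    return SegmentedSample(
        grid=grid,
        label=sample.label,
        species=sample.species,
        crop_origin=sample.crop_origin,
        source_capture=sample.source_capture,
        sample_id=f"{sample.sample_id}_aug{draw_seed}",
        parent_id=sample.sample_id,
        draw_seed=int(draw_seed),
        transform=params,
    )


def augment_dataset(
    samples: list[SegmentedSample], policy: AugmentationPolicy
) -> list[SegmentedSample]:
    """Expand the dataset to exactly ``factor x len(samples)``.

    Output order: each original followed by its ``factor - 1`` variants.
    Variant ``j`` of original ``i`` uses
    ``draw_seed = derive_child_seed(policy.seed, i * (factor - 1) + j)``.
    """
    if not samples:
        raise UsageError("augment_dataset requires a non-empty sample list")
    out: list[SegmentedSample] = []
    k = policy.factor - 1
    for i, s in enumerate(samples):
        out.append(s)
        for j in range(k):
            out.append(augment_image(s, policy, derive_child_seed(policy.seed, i * k + j)))
    return out


def write_lineage(samples: list[SegmentedSample], path: str | Path) -> None:
    """Lineage manifest CSV: variant_id, parent_id, draw_seed, transform."""
    import json

    import pandas as pd

    rows = []
    for s in samples:
        rows.append(
            {
                "variant_id": s.sample_id,
                "parent_id": s.parent_id or "",
                "draw_seed": s.draw_seed if s.draw_seed is not None else -1,
                "label": s.label,
                "species": s.species,
                "transform": json.dumps(s.transform) if s.transform else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
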