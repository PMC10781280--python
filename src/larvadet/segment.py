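"""Larva localization and fixed-size cropping.

The GRE wavelet rendering is split into R/G/B planes; because the
rendering colormap makes G monotone in intensity, the larva — the
brightest structure in the scene — sits at the global maximum of the G
plane.  The located coordinate is mapped back to source resolution and a
300x300 window centered there (clamped inside the image, never padded),
cut from the full-resolution 3-channel rendering of the band — the
original image with its channels not separated — becomes the classifier
input.

Captures where nothing stands out are filtered by a quality score,
``G.max() - median(G)``: a featureless frame has a score near the noise
amplitude and is rejected, mirroring the attrition between raw and
segmented image counts in a manually curated larva image set.  All
coordinates are 0-based (row, col) with a top-left origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, InputError
from .preprocess import WaveletImage, render_rgb, wavelet_transform
from .synthetic import MultispectralCapture

__all__ = [
    "CROP_SIZE",
    "SegmentedSample",
    "RejectionRecord",
    "split_channels",
    "locate_larva",
    "crop_centered",
    "quality_score",
    "segment_capture",
    "segment_dataset",
    "write_rejection_log",
    "save_samples",
]

#: Standardized crop side in pixels.
CROP_SIZE = 300


@dataclass
class SegmentedSample:
    """A crop_size x crop_size 3-channel crop with label and provenance."""

    grid: np.ndarray  # (S, S, 3) uint8
    label: int  # 1 = larva present, 0 = absent
    species: str
    crop_origin: tuple[int, int]  # top-left of the crop in the source image
    source_capture: str
    sample_id: str = ""
    # augmentation lineage (filled by the augmentation stage)
    parent_id: str | None = None
    draw_seed: int | None = None
    transform: dict | None = None

    def __post_init__(self) -> None:
        if self.grid.ndim != 3 or self.grid.shape[2] != 3:
            raise FormatError(f"sample grid must be (S, S, 3), got {self.grid.shape}")
        if not self.sample_id:
            self.sample_id = self.source_capture


@dataclass
class RejectionRecord:
    capture_id: str
    score: float
    threshold: float
    verdict: str  # "accept" | "reject"


def split_channels(rgb_image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a 3-channel image into (R, G, B) planes; lossless."""
    x = np.asarray(rgb_image)
    if x.ndim != 3 or x.shape[2] != 3:
        raise FormatError(f"expected a 3-channel image, got shape {x.shape}")
    return x[:, :, 0], x[:, :, 1], x[:, :, 2]


def locate_larva(g_plane: np.ndarray) -> tuple[int, int]:
    """Coordinate of the global maximum of the G plane.

    Ties break to the smallest row, then smallest column (C-order argmax).
    """
    g = np.asarray(g_plane)
    if g.ndim != 2 or g.size == 0:
        raise InputError("G plane must be a non-empty 2-D grid")
    idx = int(np.argmax(g))
    return (idx // g.shape[1], idx % g.shape[1])


def crop_centered(
    image: np.ndarray, center: tuple[int, int], size: int = CROP_SIZE
) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop a size x size window nominally centered on ``center``.

    When the nominal window overruns a border it is shifted (clamped) to
    stay inside the image, so the output is always exactly size x size and
    contains only real pixels.  Returns ``(crop, crop_origin)``.
    """
    x = np.asarray(image)
    h, w = x.shape[:2]
    if h < size or w < size:
        raise InputError(f"image {h}x{w} is smaller than the {size}x{size} crop")
    r0 = min(max(center[0] - size // 2, 0), h - size)
    c0 = min(max(center[1] - size // 2, 0), w - size)
    return x[r0 : r0 + size, c0 : c0 + size], (r0, c0)


def quality_score(g_plane: np.ndarray) -> float:
    """Feature prominence of a frame: G maximum minus G median."""
    g = np.asarray(g_plane, dtype=np.float64)
    return float(g.max() - np.median(g))


def segment_capture(
    capture: MultispectralCapture,
    wavelet: WaveletImage | None = None,
    size: int = CROP_SIZE,
    family: str = "haar",
    level: int = 1,
    band: str = "GRE",
) -> SegmentedSample:
    """Localize on the wavelet G plane, crop from the source rendering.

    Coordinates come from the G plane of the wavelet rendering; pixels
    come from the full-resolution 3-channel rendering of the unseparated
    band image.  The label is taken from the capture's ground truth when
    available (1 if a larva was planted).
    """
    if wavelet is None:
        wavelet = wavelet_transform(capture.bands[band], family, level, source_band=band)
    _, g, _ = split_channels(wavelet.rgb)
    wr, wc = locate_larva(g)
    # center of the wavelet pixel's source block
    f = 2**wavelet.level
    center = (wr * f + f // 2, wc * f + f // 2)
    source_rgb = render_rgb(capture.bands[band], wavelet.colormap)
    crop, origin = crop_centered(source_rgb, center, size)
    truth = capture.truth
    return SegmentedSample(
        grid=np.ascontiguousarray(crop),
        label=int(truth.larva_present) if truth is not None else 1,
        species=truth.species_profile if truth is not None else "",
        crop_origin=origin,
        source_capture=capture.capture_id,
    )


def segment_dataset(
    captures: list[MultispectralCapture],
    quality_threshold: float = 50.0,
    size: int = CROP_SIZE,
    family: str = "haar",
    level: int = 1,
    band: str = "GRE",
) -> tuple[list[SegmentedSample], list[RejectionRecord]]:
    """Filter captures by quality score and crop the survivors.

    A capture is accepted iff ``G.max() - median(G) >= quality_threshold``
    on its GRE wavelet rendering; each accepted capture yields one sample.
    Every capture is logged with its score and verdict, making the filter
    auditable.  The acceptance rate is non-increasing in the threshold.
    """
    samples: list[SegmentedSample] = []
    log: list[RejectionRecord] = []
    for cap in captures:
        w = wavelet_transform(cap.bands[band], family, level, source_band=band)
        _, g, _ = split_channels(w.rgb)
        score = quality_score(g)
        if score >= quality_threshold:
            samples.append(segment_capture(cap, wavelet=w, size=size))
            log.append(RejectionRecord(cap.capture_id, score, quality_threshold, "accept"))
        else:
            log.append(RejectionRecord(cap.capture_id, score, quality_threshold, "reject"))
    return samples, log


def write_rejection_log(log: list[RejectionRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "capture_id": r.capture_id,
                "score": r.score,
                "threshold": r.threshold,
                "verdict": r.verdict,
            }
            for r in log
        ]
    ).to_csv(path, index=False)


def save_samples(samples: list[SegmentedSample], outdir: str | Path) -> None:
    """Write crops as PNG under ``<outdir>/<species>/<label>/``."""
    from PIL import Image

    for s in samples:
        d = Path(outdir) / (s.species or "unknown") / str(s.label)
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(s.grid).save(d / f"{s.sample_id}.png")
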