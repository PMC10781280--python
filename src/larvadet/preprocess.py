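"""Wavelet-band preprocessing and discriminative-band selection.

Band images are converted to their 2-D wavelet approximation subband
(default: Haar, level 1), normalized back to the 8-bit intensity scale and
rendered to a 3-channel image through a fixed colormap whose green channel
is monotonically increasing in intensity.  That colormap contract is what
allows the downstream localization stage to read "bright larva" off the G
plane after RGB separation.

Per-column five-number summaries (``column_distribution``) are the
numerical form of the boxplot-per-column view in which a larva shows up as
a narrow, sharp high-value column against a flat background.  The
band-contrast score condenses that view into one number per band:
``(max - median) / (IQR + 1)`` — large when the image contains a small,
very bright feature over a low-variance background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt

from .bands import BAND_ORDER
from .exceptions import ConfigurationError, InputError, UsageError
from .synthetic import MultispectralCapture

__all__ = [
    "WaveletImage",
    "ColumnDistributionSummary",
    "wavelet_transform",
    "render_rgb",
    "column_distribution",
    "band_contrast_score",
    "select_band",
    "wavelet_to_source_coords",
]

#: Epsilon (in 8-bit intensity units) guarding the IQR division on
#: constant images.
CONTRAST_EPS = 1.0


def render_rgb(grid: np.ndarray, colormap: str = "green_ramp") -> np.ndarray:
    """Render a single-band 8-bit grid to 3 channels.

    ``green_ramp`` (the pipeline default) maps intensity v to
    ``(R, G, B) = (255 - v, v, 255 - v)``: the G channel equals the grid
    (rank order trivially preserved) while R and B mirror it, the reflected
    counterpart distributions seen when splitting the rendering.  ``gray``
    replicates v into all three channels.
    """
    g = np.asarray(grid)
    if colormap == "green_ramp":
        inv = 255 - g
        return np.stack([inv, g, inv], axis=-1).astype(np.uint8)
    if colormap == "gray":
        return np.stack([g, g, g], axis=-1).astype(np.uint8)
    raise ConfigurationError(f"unknown colormap {colormap!r}")


@dataclass
class WaveletImage:
    """A band image after wavelet conversion plus its 3-channel rendering."""

    source_band: str
    grid: np.ndarray  # 2-D uint8 approximation subband on the 8-bit scale
    rgb: np.ndarray  # (H, W, 3) uint8, pure function of grid + colormap
    wavelet_family: str
    level: int
    colormap: str = "green_ramp"

    def __post_init__(self) -> None:
        if self.grid.shape != self.rgb.shape[:2]:
            raise InputError("grid and rgb dimensions differ")


def wavelet_transform(
    band_image: np.ndarray,
    family: str = "haar",
    level: int = 1,
    colormap: str = "green_ramp",
    source_band: str = "GRE",
) -> WaveletImage:
    """Approximation subband at ``level``, rescaled to the 8-bit range.

    Periodized decomposition is used so each level halves the grid
    (``ceil(n / 2)`` per side, padding odd sides internally).  The
    approximation coefficients are divided by ``2**level``, which for Haar
    maps them exactly onto block means of the input (level 1: 2x2 blocks)
    and keeps any family on the original intensity scale; the result is
    rounded and clipped to [0, 255].
    """
    if level < 1:
        raise ConfigurationError("level must be >= 1")
    try:
        wav = pywt.Wavelet(family)
    except ValueError as e:
        raise ConfigurationError(f"unknown wavelet family {family!r}") from e
    x = np.asarray(band_image, dtype=np.float64)
    if x.ndim != 2 or x.size == 0:
        raise InputError("band image must be a non-empty 2-D grid")
    coeffs = pywt.wavedec2(x, wav, mode="periodization", level=level)
    approx = coeffs[0] / (2.0**level)
    grid = np.clip(np.rint(approx), 0, 255).astype(np.uint8)
    return WaveletImage(
        source_band=source_band,
        grid=grid,
        rgb=render_rgb(grid, colormap),
        wavelet_family=family,
        level=level,
        colormap=colormap,
    )


def wavelet_to_source_coords(coord: tuple[int, int], level: int) -> tuple[int, int]:
    """Map a wavelet-grid coordinate to the top-left of its source block."""
    f = 2**level
    return (coord[0] * f, coord[1] * f)


@dataclass
class ColumnDistributionSummary:
    """Per-column five-number summaries of pixel intensity.

    Arrays are indexed by column; quantiles use linear interpolation
    (``numpy.percentile`` default).
    """

    minimum: np.ndarray
    q1: np.ndarray
    median: np.ndarray
    q3: np.ndarray
    maximum: np.ndarray

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1

    @property
    def n_columns(self) -> int:
        return self.minimum.shape[0]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "column_index": np.arange(self.n_columns),
                "min": self.minimum,
                "q1": self.q1,
                "median": self.median,
                "q3": self.q3,
                "max": self.maximum,
            }
        ).to_csv(path, index=False)


def column_distribution(image: np.ndarray) -> ColumnDistributionSummary:
    """Exact five-number summary of every pixel column."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2 or x.size == 0:
        raise InputError("image must be a non-empty 2-D grid")
    q1, med, q3 = np.percentile(x, [25, 50, 75], axis=0)
    return ColumnDistributionSummary(
        minimum=x.min(axis=0), q1=q1, median=med, q3=q3, maximum=x.max(axis=0)
    )


def band_contrast_score(
    capture: MultispectralCapture,
    family: str = "haar",
    level: int = 1,
) -> dict[str, float]:
    """Sharp-feature score per band: ``(max - median) / (IQR + eps)``.

    Computed on each band's wavelet approximation.  A band containing a
    small, bright larva over a flat background scores high; a featureless
    band scores ~0.  Identical grids score identically.
    """
    missing = [b for b in BAND_ORDER if b not in capture.bands]
    if missing:
        raise InputError(f"capture is missing bands: {missing}")
    scores = {}
    for band in BAND_ORDER:
        w = wavelet_transform(capture.bands[band], family, level, source_band=band)
        g = w.grid.astype(np.float64)
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        scores[band] = float((g.max() - med) / ((q3 - q1) + CONTRAST_EPS))
    return scores


def select_band(
    captures: list[MultispectralCapture],
    family: str = "haar",
    level: int = 1,
) -> str:
    """Majority vote of per-capture argmax contrast scores.

    Each capture votes for its highest-scoring band; ties (within a capture
    and across the vote tally) break deterministically in the fixed band
    order ``GRE, NIR, RED, REG``.
    """
    if not captures:
        raise UsageError("select_band requires at least one capture")
    votes = {b: 0 for b in BAND_ORDER}
    for cap in captures:
        scores = band_contrast_score(cap, family, level)
        best = max(BAND_ORDER, key=lambda b: (scores[b], -BAND_ORDER.index(b)))
        votes[best] += 1
    return max(BAND_ORDER, key=lambda b: (votes[b], -BAND_ORDER.index(b)))
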