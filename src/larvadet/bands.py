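"""Spectral band metadata for the four-band multispectral imager.

The imager records four co-registered monochrome bands: green (GRE),
near-infrared (NIR), red (RED) and red-edge (REG).  Band names double as
keys throughout the pipeline; ``BAND_ORDER`` is the canonical ordering and
also the deterministic tie-break order used by band selection.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """One spectral band: name, center wavelength and bandwidth in nm."""

    name: str
    center_wavelength: float
    bandwidth: float


#: Canonical band ordering (also the band-selection tie-break order).
BAND_ORDER: tuple[str, ...] = ("GRE", "NIR", "RED", "REG")

#: The four bands of the imaging setup, keyed by name.
BANDS: dict[str, BandSpec] = {
    "GRE": BandSpec("GRE", 550.0, 40.0),
    "RED": BandSpec("RED", 660.0, 40.0),
    "REG": BandSpec("REG", 735.0, 10.0),
    "NIR": BandSpec("NIR", 790.0, 40.0),
}
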