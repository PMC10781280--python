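"""Seeded synthetic multispectral scene generator.

Each scene is a dark, low-variance background with (optionally) one larva:
a narrow, elongated, slightly curved capsule of elevated intensity.  The
larva's contrast over the background differs per band and is strongest in
the green (GRE) band, which is the statistical structure the preprocessing
stages assume.  Additive Gaussian "conversion" noise, clipped to the 8-bit
range, is applied independently per band.

All randomness flows through :class:`numpy.random.Generator` instances
seeded explicitly, and dataset generation derives one child seed per
capture from the master seed with a fixed mixing rule
(``child = (master * 1_000_003 + index) mod (2**31 - 1)``), so any capture
can be regenerated bit-exactly in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bands import BAND_ORDER
from .exceptions import SceneError, UsageError

__all__ = [
    "SceneSpec",
    "MultispectralCapture",
    "SPECIES_PROFILES",
    "DEFAULT_BAND_CONTRAST",
    "generate_capture",
    "generate_dataset",
    "random_scene_spec",
    "larva_mask",
    "derive_child_seed",
    "save_capture",
    "load_capture",
    "write_manifest",
]

#: Default per-band intensity lift of the larva over the background, as a
#: fraction of the full 8-bit range.  GRE is strictly dominant by design.
DEFAULT_BAND_CONTRAST: dict[str, float] = {
    "GRE": 0.6,
    "NIR": 0.25,
    "REG": 0.2,
    "RED": 0.15,
}

#: Per-species geometry ranges (pixels / fraction).  Chironomid larvae are
#: the longest and thinnest; mosquito larvae the shortest.  Curvature is the
#: bow height of the capsule centerline as a fraction of its length.
SPECIES_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "chironomid": {"length": (60.0, 90.0), "width": (4.0, 7.0), "curvature": (0.05, 0.20)},
    "yellow_worm": {"length": (40.0, 70.0), "width": (8.0, 14.0), "curvature": (0.02, 0.12)},
    "mosquito": {"length": (30.0, 55.0), "width": (6.0, 10.0), "curvature": (0.02, 0.10)},
}

#: Maximum extent of the larva bounding box (the observation window).
MAX_LARVA_BOX = 100


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    The larva is rendered as an anti-aliased thick curve (a capsule with an
    optional quadratic bow); ``larva_center`` is the midpoint of its
    centerline in 0-based (row, col) coordinates.
    """

    image_side: int = 1200
    larva_length: float = 75.0
    larva_width: float = 5.0
    larva_orientation: float = 30.0  # degrees, 0 = horizontal
    larva_curvature: float = 0.1  # bow height / length
    larva_center: tuple[float, float] = (600.0, 600.0)
    band_contrast: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_CONTRAST)
    )
    background_level: float = 30.0
    noise_sd: float = 5.0
    larva_present: bool = True
    species_profile: str = "chironomid"

    def validate(self) -> None:
        if self.image_side < 1:
            raise SceneError("image_side must be positive")
        if set(self.band_contrast) != set(BAND_ORDER):
            raise SceneError(f"band_contrast must define exactly the bands {BAND_ORDER}")
        for b, c in self.band_contrast.items():
            if not 0.0 <= c <= 1.0:
                raise SceneError(f"band_contrast[{b}]={c} outside [0, 1]")
        gre = self.band_contrast["GRE"]
        others = [self.band_contrast[b] for b in BAND_ORDER if b != "GRE"]
        if not all(gre > c for c in others):
            raise SceneError("band_contrast['GRE'] must strictly exceed every other band")
        if self.species_profile not in SPECIES_PROFILES:
            raise SceneError(f"unknown species_profile {self.species_profile!r}")
        if self.noise_sd < 0:
            raise SceneError("noise_sd must be non-negative")
        if not self.larva_present:
            return
        if not self.larva_width < self.larva_length:
            raise SceneError("larva must be elongated: width < length")
        r0, r1, c0, c1 = self._bounding_box()
        if (r1 - r0) > MAX_LARVA_BOX or (c1 - c0) > MAX_LARVA_BOX:
            raise SceneError(
                f"larva bounding box {r1 - r0:.0f}x{c1 - c0:.0f} exceeds the "
                f"{MAX_LARVA_BOX}x{MAX_LARVA_BOX} observation window"
            )
        if r0 < 0 or c0 < 0 or r1 > self.image_side or c1 > self.image_side:
            raise SceneError(
                "larva bounding box extends outside the image; move larva_center inward"
            )

    # -- geometry ---------------------------------------------------------

    def centerline(self, n_points: int = 64) -> np.ndarray:
        """Sampled centerline points, shape (n_points, 2) as (row, col)."""
        t = np.linspace(-0.5, 0.5, n_points)
        theta = np.deg2rad(self.larva_orientation)
        d = np.array([np.sin(theta), np.cos(theta)])  # along-axis direction
        p = np.array([-np.cos(theta), np.sin(theta)])  # perpendicular
        bow = self.larva_curvature * self.larva_length * (1.0 - 4.0 * t**2)
        pts = (
            np.asarray(self.larva_center)[None, :]
            + t[:, None] * self.larva_length * d[None, :]
            + bow[:, None] * p[None, :]
        )
        return pts

    def _bounding_box(self) -> tuple[float, float, float, float]:
        pts = self.centerline()
        half = self.larva_width / 2.0 + 1.0  # +1 px anti-aliasing margin
        r0 = float(pts[:, 0].min() - half)
        r1 = float(pts[:, 0].max() + half)
        c0 = float(pts[:, 1].min() - half)
        c1 = float(pts[:, 1].max() + half)
        return r0, r1, c0, c1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SceneSpec":
        d = json.loads(s)
        d["larva_center"] = tuple(d["larva_center"])
        return cls(**d)


@dataclass
class MultispectralCapture:
    """One scene as four co-registered 8-bit band images plus ground truth.

    ``truth`` is the :class:`SceneSpec` for synthetic captures and ``None``
    for captures loaded without an annotation sidecar.  ``seed`` is the
    per-capture seed used to generate it (when synthetic), so
    ``generate_capture(capture.truth, capture.seed)`` reproduces it.
    """

    bands: dict[str, np.ndarray]
    truth: SceneSpec | None
    capture_id: str
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {b: g.shape for b, g in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise SceneError(f"band grids differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def truth_mask(self) -> np.ndarray | None:
        """Boolean larva mask at full resolution, or None if unknown/absent."""
        if self.truth is None or not self.truth.larva_present:
            return None
        return larva_mask(self.truth)


def _alpha_window(spec: SceneSpec) -> tuple[np.ndarray, int, int]:
    """Anti-aliased larva coverage on a local window.

    Returns (alpha, row0, col0) where alpha is the per-pixel coverage in
    [0, 1] of the capsule of width ``larva_width`` around the centerline,
    computed from the distance to the sampled polyline.
    """
    pts = spec.centerline()
    half = spec.larva_width / 2.0
    pad = int(np.ceil(half + 2.0))
    r0 = max(int(np.floor(pts[:, 0].min())) - pad, 0)
    r1 = min(int(np.ceil(pts[:, 0].max())) + pad + 1, spec.image_side)
    c0 = max(int(np.floor(pts[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(pts[:, 1].max())) + pad + 1, spec.image_side)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    px = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)

    # distance from every window pixel to the polyline (segment-wise)
    a = pts[:-1]  # (S,2)
    b = pts[1:]
    ab = b - a
    ab2 = (ab**2).sum(axis=1)
    ab2[ab2 == 0] = 1e-12
    # (P,S,2) differences
    ap = px[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.sqrt(((px[:, None, :] - proj) ** 2).sum(axis=2)).min(axis=1)

    alpha = np.clip(half + 0.5 - d, 0.0, 1.0).reshape(rr.shape)
    return alpha, r0, c0


def larva_mask(spec: SceneSpec) -> np.ndarray:
    """Boolean mask of pixels that are at least half covered by the larva."""
    spec.validate()
    mask = np.zeros((spec.image_side, spec.image_side), dtype=bool)
    if spec.larva_present:
        alpha, r0, c0 = _alpha_window(spec)
        mask[r0 : r0 + alpha.shape[0], c0 : c0 + alpha.shape[1]] = alpha > 0.5
    return mask


def generate_capture(spec: SceneSpec, seed: int) -> MultispectralCapture:
    """Render one capture: background + per-band larva lift + clipped noise.

    Deterministic for fixed ``(spec, seed)``.  Larva pixels exceed the
    background by ``band_contrast[band] * 255`` (scaled by anti-aliased
    coverage) before noise; noise is additive Gaussian with standard
    deviation ``spec.noise_sd``, drawn independently per band in the fixed
    band order, and the result is clipped to [0, 255] and quantized.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise SceneError("seed must be a non-negative integer")
    spec.validate()
    rng = np.random.default_rng(int(seed))
    side = spec.image_side

    if spec.larva_present:
        alpha, r0, c0 = _alpha_window(spec)
    bands: dict[str, np.ndarray] = {}
    for band in BAND_ORDER:
        img = np.full((side, side), spec.background_level, dtype=np.float64)
        if spec.larva_present:
            img[r0 : r0 + alpha.shape[0], c0 : c0 + alpha.shape[1]] += (
                alpha * spec.band_contrast[band] * 255.0
            )
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        bands[band] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return MultispectralCapture(
        bands=bands,
        truth=spec,
        capture_id=f"{spec.species_profile}_s{int(seed):010d}",
        seed=int(seed),
    )


def derive_child_seed(master_seed: int, index: int) -> int:
    """Fixed documented mixing rule for per-capture seeds (< 2**31)."""
    return (int(master_seed) * 1_000_003 + int(index)) % (2**31 - 1)


def random_scene_spec(
    species: str,
    rng: np.random.Generator,
    larva_present: bool = True,
    image_side: int = 1200,
    band_contrast: dict[str, float] | None = None,
    background_level: float = 30.0,
    noise_sd: float = 5.0,
) -> SceneSpec:
    """Draw a scene with species-specific larva geometry.

    Geometry ranges come from :data:`SPECIES_PROFILES`; orientation is
    uniform over [0, 180) degrees and the center is uniform over the image
    interior with a margin that keeps the bounding box inside the frame.
    """
    prof = SPECIES_PROFILES[species]
    length = rng.uniform(*prof["length"])
    width = rng.uniform(*prof["width"])
    curvature = rng.uniform(*prof["curvature"])
    orientation = rng.uniform(0.0, 180.0)
    # keep the worst-case bounding box (half length + bow + half width +
    # anti-aliasing margin) inside the frame
    margin = (
        prof["length"][1] / 2.0
        + prof["curvature"][1] * prof["length"][1]
        + prof["width"][1] / 2.0
        + 3.0
    )
    center = tuple(rng.uniform(margin, image_side - margin, size=2))
    return SceneSpec(
        image_side=image_side,
        larva_length=length,
        larva_width=width,
        larva_orientation=orientation,
        larva_curvature=curvature,
        larva_center=center,
        band_contrast=dict(band_contrast or DEFAULT_BAND_CONTRAST),
        background_level=background_level,
        noise_sd=noise_sd,
        larva_present=larva_present,
        species_profile=species,
    )


def generate_dataset(
    n_present: int,
    n_absent: int,
    species: str = "chironomid",
    seed: int = 0,
    **scene_kwargs,
) -> list[MultispectralCapture]:
    """Generate ``n_present`` larva scenes followed by ``n_absent`` blanks.

    Capture ``i`` uses child seed ``derive_child_seed(seed, i)`` both for
    its geometry draw and its pixel noise, so it can be regenerated alone:
    ``generate_capture(captures[i].truth, captures[i].seed)`` is bit-exact.
    """
    if n_present < 0 or n_absent < 0:
        raise UsageError(f"counts must be non-negative, got ({n_present}, {n_absent})")
    captures = []
    for i in range(n_present + n_absent):
        child = derive_child_seed(seed, i)
        rng = np.random.default_rng(child)
        spec = random_scene_spec(
            species, rng, larva_present=(i < n_present), **scene_kwargs
        )
        cap = generate_capture(spec, child)
        cap.capture_id = f"{species}_{i:04d}_s{child:010d}"
        captures.append(cap)
    return captures


# -- on-disk representation -----------------------------------------------


def save_capture(capture: MultispectralCapture, outdir: str | Path, fmt: str = "tif") -> None:
    """Write one image per band plus a JSON truth sidecar.

    Layout: ``<capture_id>_<BAND>.tif`` (or ``.png``) and
    ``<capture_id>_truth.json`` when ground truth is known.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for band, grid in capture.bands.items():
        path = outdir / f"{capture.capture_id}_{band}.{fmt}"
        if fmt == "tif":
            import tifffile

            tifffile.imwrite(path, grid)
        else:
            from PIL import Image

            Image.fromarray(grid).save(path)
    if capture.truth is not None:
        sidecar = {"scene": json.loads(capture.truth.to_json()), "seed": capture.seed}
        (outdir / f"{capture.capture_id}_truth.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )


def load_capture(capture_id: str, indir: str | Path, fmt: str = "tif") -> MultispectralCapture:
    """Load a capture written by :func:`save_capture`."""
    indir = Path(indir)
    bands = {}
    for band in BAND_ORDER:
        path = indir / f"{capture_id}_{band}.{fmt}"
        if fmt == "tif":
            import tifffile

            bands[band] = tifffile.imread(path)
        else:
            from PIL import Image

            bands[band] = np.asarray(Image.open(path))
    truth = None
    seed = None
    sidecar = indir / f"{capture_id}_truth.json"
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        truth = SceneSpec.from_json(json.dumps(d["scene"]))
        seed = d["seed"]
    return MultispectralCapture(bands=bands, truth=truth, capture_id=capture_id, seed=seed)


def write_manifest(captures: list[MultispectralCapture], path: str | Path) -> None:
    """Dataset manifest CSV: capture_id, label, species, seed."""
    import pandas as pd

    rows = [
        {
            "capture_id": c.capture_id,
            "label": int(c.truth.larva_present) if c.truth else -1,
            "species": c.truth.species_profile if c.truth else "",
            "seed": c.seed if c.seed is not None else -1,
        }
        for c in captures
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
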