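"""Synthetic capture generator: determinism, geometry, contrast structure."""

import numpy as np
import pytest

from larvadet.bands import BAND_ORDER, BANDS
from larvadet.exceptions import SceneError, UsageError
from larvadet.synthetic import (
    SceneSpec,
    derive_child_seed,
    generate_capture,
    generate_dataset,
    larva_mask,
    load_capture,
    random_scene_spec,
    save_capture,
)


def test_band_registry_matches_imager():
    assert set(BANDS) == {"GRE", "NIR", "RED", "REG"}
    assert BANDS["GRE"].center_wavelength == 550 and BANDS["GRE"].bandwidth == 40
    assert BANDS["RED"].center_wavelength == 660 and BANDS["RED"].bandwidth == 40
    assert BANDS["REG"].center_wavelength == 735 and BANDS["REG"].bandwidth == 10
    assert BANDS["NIR"].center_wavelength == 790 and BANDS["NIR"].bandwidth == 40


def test_blank_noiseless_capture_is_constant_background():
    spec = SceneSpec(image_side=64, larva_present=False, noise_sd=0.0, background_level=30)
    cap = generate_capture(spec, seed=0)
    for band in BAND_ORDER:
        assert cap.bands[band].shape == (64, 64)
        assert np.all(cap.bands[band] == 30)


def test_same_spec_and_seed_is_bit_identical(small_scene):
    a = generate_capture(small_scene, seed=3)
    b = generate_capture(small_scene, seed=3)
    for band in BAND_ORDER:
        np.testing.assert_array_equal(a.bands[band], b.bands[band])
    c = generate_capture(small_scene, seed=4)
    assert any(not np.array_equal(a.bands[b_], c.bands[b_]) for b_ in BAND_ORDER)


def test_gre_contrast_gap_is_largest(small_scene):
    cap = generate_capture(small_scene, seed=11)
    mask = larva_mask(small_scene)
    gaps = {}
    for band in BAND_ORDER:
        g = cap.bands[band].astype(float)
        gaps[band] = g[mask].mean() - g[~mask].mean()
    assert all(gaps["GRE"] > gaps[b] for b in BAND_ORDER if b != "GRE")


def test_contrast_ordering_holds_across_random_scenes():
    """GRE larva/background gap beats every other band in 100/100 scenes."""
    caps = generate_dataset(100, 0, "chironomid", seed=5, image_side=300)
    wins = 0
    for cap in caps:
        mask = cap.truth_mask()
        gaps = {
            b: cap.bands[b][mask].astype(float).mean() - cap.bands[b][~mask].astype(float).mean()
            for b in BAND_ORDER
        }
        wins += all(gaps["GRE"] > gaps[b] for b in BAND_ORDER if b != "GRE")
    assert wins == 100


def test_planted_centroid_recoverable_from_noiseless_gre():
    """The larva centroid is where the 100x100 window mean peaks."""
    spec = SceneSpec(
        image_side=400,
        larva_center=(150.0, 260.0),
        noise_sd=0.0,
    )
    cap = generate_capture(spec, seed=0)
    g = cap.bands["GRE"].astype(np.float64)
    # box-filter the grid with a 100x100 window via cumulative sums
    cs = np.cumsum(np.cumsum(np.pad(g, ((1, 0), (1, 0))), axis=0), axis=1)
    w = 100
    sums = cs[w:, w:] - cs[:-w, w:] - cs[w:, :-w] + cs[:-w, :-w]
    # noiseless: every window fully containing the larva ties for the
    # maximum, so compare their mean center with the planted centroid
    rr, cc = np.nonzero(sums == sums.max())
    window_center = (rr.mean() + w / 2, cc.mean() + w / 2)
    assert abs(window_center[0] - 150.0) < 10
    assert abs(window_center[1] - 260.0) < 10


def test_larva_bounding_box_constraints():
    with pytest.raises(SceneError, match="observation window"):
        SceneSpec(larva_length=140.0, larva_width=5.0).validate()
    with pytest.raises(SceneError, match="outside the image"):
        SceneSpec(larva_center=(10.0, 10.0)).validate()
    with pytest.raises(SceneError, match="elongated"):
        SceneSpec(larva_length=10.0, larva_width=12.0).validate()
    with pytest.raises(SceneError, match="strictly exceed"):
        SceneSpec(band_contrast={"GRE": 0.2, "NIR": 0.2, "RED": 0.1, "REG": 0.1}).validate()


def test_generate_capture_rejects_bad_seed(small_scene):
    with pytest.raises(SceneError):
        generate_capture(small_scene, seed=-1)


@pytest.mark.parametrize(
    "n_present,n_absent", [(0, 5), (3, 2)]
)
def test_dataset_counts_and_labels(n_present, n_absent):
    caps = generate_dataset(n_present, n_absent, "chironomid", seed=1, image_side=300)
    assert len(caps) == n_present + n_absent
    labels = [c.truth.larva_present for c in caps]
    assert labels == [True] * n_present + [False] * n_absent


def test_dataset_capture_regenerable_from_child_seed():
    caps = generate_dataset(3, 2, "mosquito", seed=42, image_side=300)
    cap = caps[3]
    assert cap.seed == derive_child_seed(42, 3)
    redo = generate_capture(cap.truth, cap.seed)
    for band in BAND_ORDER:
        np.testing.assert_array_equal(cap.bands[band], redo.bands[band])


def test_dataset_rejects_negative_counts():
    with pytest.raises(UsageError):
        generate_dataset(-1, 2, "chironomid", seed=0)


def test_species_geometry_ranges():
    rng = np.random.default_rng(0)
    chiro = [random_scene_spec("chironomid", rng, image_side=300) for _ in range(20)]
    mosq = [random_scene_spec("mosquito", rng, image_side=300) for _ in range(20)]
    assert min(s.larva_length for s in chiro) > max(s.larva_width for s in chiro)
    # chironomids are longer and thinner than mosquito larvae on average
    assert np.mean([s.larva_length for s in chiro]) > np.mean([s.larva_length for s in mosq])
    assert np.mean([s.larva_width for s in chiro]) < np.mean([s.larva_width for s in mosq])


def test_capture_roundtrip_tiff(tmp_path, small_capture):
    save_capture(small_capture, tmp_path)
    back = load_capture(small_capture.capture_id, tmp_path)
    for band in BAND_ORDER:
        np.testing.assert_array_equal(small_capture.bands[band], back.bands[band])
    assert back.truth == small_capture.truth
    assert back.seed == small_capture.seed
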