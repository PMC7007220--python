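"""Dendritic orientation: grid fractions, dorsal share, midline crossing."""

import numpy as np
import pytest

from phrenic.dendrites import (
    DEFAULT_GRID_LAYOUT,
    DendriteImage,
    coverage_area,
    dorsal_fraction,
    grid_quantify,
    midline_crossing_stats,
)
from phrenic.synth import simulate_dendrite_image


def _image(intensity, pixel=1.0, centroid=None, midline=10.0):
    h, w = intensity.shape
    centroid = centroid or (h / 2.0, w / 2.0)
    return DendriteImage(np.asarray(intensity, float), pixel, centroid, midline)


# ---------------------------------------------------------------------------
# grid quantification


def test_uniform_intensity_gives_equal_eighths():
    """Uniform field: each peripheral square holds exactly one eighth.

    Span chosen so square boundaries fall on pixel edges (cell = 100 px),
    making the symmetry exact rather than within pixel quantization.
    """
    di = DendriteImage(np.ones((400, 400)), 1.0, (200.0, 200.0), 10.0)
    gq = grid_quantify(di, span_um=150.0)
    for sq in range(1, 9):
        assert gq.fractions[sq] == pytest.approx(0.125, abs=1e-9)
    assert sum(gq.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_all_intensity_in_dorsolateral_pair():
    """Signal confined to the dorsolateral quadrant lands in squares 5+6."""
    img = np.zeros((300, 300))
    img[55:115, 120:245] = 1.0  # dorsal band rows; centre-to-lateral columns
    di = DendriteImage(img, 2.0, (150.0, 150.0), 10.0)
    gq = grid_quantify(di)
    assert gq.fractions[5] + gq.fractions[6] == pytest.approx(1.0)


def test_grid_fractions_equal_direct_pixel_sums():
    """Oracle equivalence: fractions match brute-force per-square sums."""
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 1, (300, 300))
    di = DendriteImage(img, 2.0, (151.0, 148.0), 10.0)
    gq = grid_quantify(di)
    # independent pixel-sum path: explicit square boundaries
    half_px, cell = 100.0, 200.0 / 3.0
    r0, c0 = di.soma_centroid
    sums = {}
    for rb in range(3):
        for cb in range(3):
            if (rb, cb) == (1, 1):
                continue
            lo_r, hi_r = r0 - half_px + rb * cell, r0 - half_px + (rb + 1) * cell
            lo_c, hi_c = c0 - half_px + cb * cell, c0 - half_px + (cb + 1) * cell
            total = 0.0
            for r in range(int(np.floor(lo_r)) - 1, int(np.ceil(hi_r)) + 1):
                if not (lo_r <= r < hi_r):
                    continue
                for c in range(int(np.floor(lo_c)) - 1, int(np.ceil(hi_c)) + 1):
                    if lo_c <= c < hi_c:
                        total += img[r, c]
            sums[DEFAULT_GRID_LAYOUT[(rb, cb)]] = total
    norm = sum(sums.values())
    for sq in range(1, 9):
        assert gq.fractions[sq] == pytest.approx(sums[sq] / norm, abs=1e-12)


def test_grid_invariant_to_intensity_scaling():
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 1, (300, 300))
    a = grid_quantify(DendriteImage(img, 2.0, (150.0, 150.0), 10.0))
    b = grid_quantify(DendriteImage(9.5 * img, 2.0, (150.0, 150.0), 10.0))
    for sq in range(1, 9):
        assert a.fractions[sq] == pytest.approx(b.fractions[sq])


def test_zero_peripheral_signal_raises():
    img = np.zeros((300, 300))
    img[149:152, 149:152] = 1.0  # only the centre square
    with pytest.raises(ValueError, match="no dendritic signal"):
        grid_quantify(DendriteImage(img, 2.0, (150.0, 150.0), 10.0))


def test_clipped_grid_warns():
    di = DendriteImage(np.ones((80, 80)), 2.0, (40.0, 40.0), 5.0)
    with pytest.warns(UserWarning, match="clipped"):
        grid_quantify(di)


def test_simulated_fractions_recovered_across_seeds():
    """Grid fractions match analytic ground truth within 0.03, 20 seeds."""
    for seed in range(20):
        sim = simulate_dendrite_image(seed=seed)
        gq = grid_quantify(sim.image)
        for sq in range(1, 9):
            assert gq.fractions[sq] == pytest.approx(
                sim.square_fractions[sq], abs=0.03)


# ---------------------------------------------------------------------------
# dorsal fraction


def test_dorsal_fraction_extremes():
    img = np.zeros((100, 50))
    img[:40, :] = 1.0
    di = _image(img, centroid=(50.0, 25.0), midline=2.0)
    assert dorsal_fraction(di) == pytest.approx(1.0)
    img2 = np.zeros((100, 50))
    img2[60:, :] = 1.0
    di2 = _image(img2, centroid=(50.0, 25.0), midline=2.0)
    assert dorsal_fraction(di2) == pytest.approx(0.0)


def test_dorsal_plus_ventral_is_one():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 1, (120, 80))
    di = _image(img, centroid=(60.0, 40.0), midline=2.0)
    dorsal = dorsal_fraction(di)
    ventral = img[60:, :].sum() / img.sum()
    assert dorsal + ventral == pytest.approx(1.0)


def test_simulated_dorsal_share_recovered():
    sim = simulate_dendrite_image(seed=4)
    assert dorsal_fraction(sim.image) == pytest.approx(
        sim.dorsal_fraction, abs=0.02)


# ---------------------------------------------------------------------------
# midline crossing


def test_strictly_ipsilateral_image_has_no_crossings():
    sim = simulate_dendrite_image(contralateral_extent_um=0.0, seed=0)
    ms = midline_crossing_stats(sim.image)
    assert ms.n_crossing_components == 0
    assert ms.max_contralateral_distance_um == 0.0
    assert not ms.crossing_flag


@pytest.mark.parametrize("extent", [30.0, 50.0])
def test_crossing_ray_distance_recovered(extent):
    sim = simulate_dendrite_image(contralateral_extent_um=extent, seed=2)
    ms = midline_crossing_stats(sim.image)
    assert ms.n_crossing_components >= 1
    assert ms.max_contralateral_distance_um == pytest.approx(
        extent, abs=sim.image.pixel_size_um)


def test_two_disjoint_crossing_components_counted():
    """Connected-component oracle: two separate bridges over the midline."""
    img = np.zeros((100, 100))
    img[20:23, 30:70] = 1.0
    img[60:63, 30:70] = 1.0
    di = DendriteImage(img, 1.0, (50.0, 70.0), 50.0)
    ms = midline_crossing_stats(di, threshold_method="fixed", threshold=0.5)
    assert ms.n_crossing_components == 2
    assert ms.max_contralateral_distance_um == pytest.approx(20.0)


def test_midline_stats_invariant_to_reflection():
    """Mirroring ipsi/contra about the midline preserves the statistics."""
    sim = simulate_dendrite_image(contralateral_extent_um=40.0, seed=6)
    di = sim.image
    ms = midline_crossing_stats(di)
    w = di.intensity.shape[1]
    mid = di.midline_col
    # reflect columns about the midline, cropping to stay inside the frame
    cols = np.arange(w)
    ref_cols = np.clip(np.round(2 * mid - cols).astype(int), 0, w - 1)
    reflected = di.intensity[:, ref_cols]
    di_ref = DendriteImage(reflected, di.pixel_size_um,
                           (di.soma_centroid[0],
                            float(np.clip(2 * mid - di.soma_centroid[1], 0, w - 1))),
                           mid)
    ms_ref = midline_crossing_stats(di_ref)
    assert ms_ref.n_crossing_components == ms.n_crossing_components
    assert ms_ref.max_contralateral_distance_um == pytest.approx(
        ms.max_contralateral_distance_um, abs=2 * di.pixel_size_um)


# ---------------------------------------------------------------------------
# coverage


def test_coverage_zero_and_rectangle():
    di = _image(np.zeros((50, 50)))
    assert coverage_area(di) == 0.0
    img = np.zeros((50, 50))
    img[10:20, 5:25] = 1.0
    di2 = _image(img)
    assert coverage_area(di2, "fixed", threshold=0.5) == pytest.approx(200.0)


def test_simulated_footprint_within_ten_percent():
    sim = simulate_dendrite_image(seed=8)
    cov = coverage_area(sim.image, "fixed", threshold=sim.footprint_threshold)
    assert cov == pytest.approx(sim.footprint_um2, rel=0.10)
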