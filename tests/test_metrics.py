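"""Stain separation, nucleus/membrane quantification, and quality metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from virtualher2 import metrics
from virtualher2.types import DegenerateThresholdError


# -- color deconvolution ----------------------------------------------------


def test_white_pixel_separates_to_zero():
    rgb = np.ones((4, 4, 3))
    sep = metrics.separate_stains(rgb)
    assert sep.hematoxylin_od.max() == 0.0
    assert sep.dab_od.max() == 0.0


def test_render_separate_roundtrip():
    hema = np.full((8, 8), 0.5)
    dab = np.zeros((8, 8))
    rgb = metrics.beer_lambert_rgb(hema, dab)
    sep = metrics.separate_stains(rgb)
    np.testing.assert_allclose(sep.hematoxylin_od, 0.5, atol=1e-6)
    assert sep.dab_od.max() <= 1e-6


def test_separation_linearity():
    d1 = metrics.separate_stains(
        metrics.beer_lambert_rgb(np.zeros((2, 2)), np.full((2, 2), 0.3))
    ).dab_od
    d2 = metrics.separate_stains(
        metrics.beer_lambert_rgb(np.zeros((2, 2)), np.full((2, 2), 0.6))
    ).dab_od
    np.testing.assert_allclose(d2, 2 * d1, rtol=1e-6)


def test_roundtrip_error_on_mixed_densities(rng):
    hema = rng.random((32, 32)) * 0.8
    dab = rng.random((32, 32)) * 0.8
    rgb = metrics.beer_lambert_rgb(hema, dab)
    sep = metrics.separate_stains(rgb)
    assert np.abs(sep.hematoxylin_od - hema).max() < 1e-3
    assert np.abs(sep.dab_od - dab).max() < 1e-3


def test_singular_matrix_rejected():
    bad = np.ones((3, 3))
    with pytest.raises(ValueError):
        metrics.separate_stains(np.ones((2, 2, 3)), stain_matrix=bad)


# -- nucleus statistics -----------------------------------------------------


def _disk_image(centers, radius, shape):
    img = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    return img


def brute_force_components(mask):
    """Flood-fill connected components (8-connectivity) without skimage."""
    mask = mask.copy()
    H, W = mask.shape
    sizes = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            stack, size = [(i, j)], 0
            mask[i, j] = False
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr_, cc_ = r + dr, c + dc
                        if 0 <= rr_ < H and 0 <= cc_ < W and mask[rr_, cc_]:
                            mask[rr_, cc_] = False
                            stack.append((rr_, cc_))
            sizes.append(size)
    return sizes


def test_nucleus_stats_on_disk_grid():
    centers = [(r, c) for r in range(16, 96, 16) for c in range(16, 96, 16)]
    disks = _disk_image(centers, 6, (112, 112))
    sep = metrics.StainSeparation(
        hematoxylin_od=disks * 0.7, dab_od=np.zeros_like(disks, dtype=float),
        residual_od=np.zeros_like(disks, dtype=float),
        stain_matrix=metrics.DEFAULT_STAIN_MATRIX,
    )
    stats = metrics.nucleus_stats(sep, opening_radius=1, min_area=10)
    sizes = brute_force_components(disks)
    assert stats.count == len(centers) == len(sizes)
    assert stats.mean_area == pytest.approx(np.mean(sizes), rel=0.1)


def test_component_counts_match_flood_fill_oracle(rng):
    for _ in range(5):
        mask = rng.random((64, 64)) > 0.7
        sizes = brute_force_components(mask)
        from skimage.measure import label

        labels = label(mask, connectivity=2)
        assert labels.max() == len(sizes)
        got = sorted(np.bincount(labels.ravel())[1:].tolist())
        assert got == sorted(sizes)


def test_constant_hematoxylin_raises():
    sep = metrics.StainSeparation(
        hematoxylin_od=np.zeros((16, 16)), dab_od=np.zeros((16, 16)),
        residual_od=np.zeros((16, 16)), stain_matrix=metrics.DEFAULT_STAIN_MATRIX,
    )
    with pytest.raises(DegenerateThresholdError):
        metrics.nucleus_stats(sep)


def test_otsu_threshold_between_two_deltas():
    from skimage.filters import threshold_otsu

    vals = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
    # exhaustive between-class variance search as the oracle
    candidates = np.linspace(0.01, 0.99, 197)
    best = max(
        candidates,
        key=lambda t: (vals < t).mean() * (vals >= t).mean()
        * (vals[vals < t].mean() - vals[vals >= t].mean()) ** 2
        if 0 < (vals < t).mean() < 1 else -1,
    )
    t_sk = threshold_otsu(vals)
    assert 0.2 < t_sk < 0.8 and 0.2 < best < 0.8


# -- characteristic curve ---------------------------------------------------


def test_characteristic_curve_constant_blob():
    sat = np.zeros((100, 100))
    sat[10:50, 20:45] = 0.9  # one blob, exactly 10% of pixels
    cc = metrics.characteristic_curve_from_saturation(sat)
    assert cc.s_values.size == 21
    np.testing.assert_allclose(cc.area_ratio, 0.1)
    assert cc.auc == pytest.approx(0.1 * 0.4, abs=1e-12)
    assert cc.connectedness == pytest.approx(0.1, abs=1e-12)


def test_characteristic_curve_two_blobs_connectedness():
    sat = np.zeros((100, 100))
    sat[0:20, 0:30] = 0.9  # 6%
    sat[60:80, 60:80] = 0.9  # 4%
    cc = metrics.characteristic_curve_from_saturation(sat)
    assert cc.connectedness == pytest.approx(0.06, abs=1e-12)


def test_dab_free_tile_flat_curve():
    sep = metrics.separate_stains(np.ones((32, 32, 3)))
    cc = metrics.membrane_stats(sep)
    assert cc.auc == 0.0 and cc.connectedness == 0.0
    assert cc.area_ratio.max() == 0.0


@settings(max_examples=25, deadline=None)
@given(hst.integers(min_value=0, max_value=2**31 - 1))
def test_area_ratio_non_increasing(seed):
    sat = np.random.default_rng(seed).random((32, 32))
    cc = metrics.characteristic_curve_from_saturation(sat)
    assert np.all(np.diff(cc.area_ratio) <= 1e-12)
    largest_at_conn = cc.connectedness
    ratio_at_conn = (sat > 0.25).mean()
    assert largest_at_conn <= ratio_at_conn + 1e-12


def test_curve_validation():
    with pytest.raises(ValueError):
        metrics.characteristic_curve_from_saturation(np.zeros((4, 4)), s_grid=np.array([]))
    with pytest.raises(ValueError):
        metrics.characteristic_curve_from_saturation(np.zeros((4, 4)), s_grid=np.array([1.5]))


# -- image quality ----------------------------------------------------------


def test_image_quality_identical(pair_grade2):
    q = metrics.image_quality(pair_grade2.ihc, pair_grade2.ihc)
    assert q.psnr == 100.0
    assert q.ssim == pytest.approx(1.0, abs=1e-9)
    assert q.ssim_dab == pytest.approx(1.0, abs=1e-9)


def test_psnr_uniform_offset_and_symmetry(rng):
    a = np.full((32, 32, 3), 0.4)
    b = a + 0.1
    q = metrics.image_quality(a, b)
    assert q.psnr == pytest.approx(20.0, abs=1e-9)
    q2 = metrics.image_quality(b, a)
    assert q.psnr == q2.psnr


def test_quality_shape_mismatch():
    with pytest.raises(ValueError):
        metrics.image_quality(np.zeros((4, 4, 3)), np.zeros((5, 5, 3)))


# -- color histograms -------------------------------------------------------


def test_color_histogram_normalization(pair_grade3):
    sep = metrics.separate_stains(pair_grade3.ihc)
    hists = metrics.color_histogram(sep, bins=48, bandwidth=0.05)
    for h in hists.values():
        assert h.raw_frequency.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.smoothed_profile.sum() == pytest.approx(1.0, abs=0.01)


def test_color_histogram_constant_channel():
    sep = metrics.StainSeparation(
        hematoxylin_od=np.full((16, 16), 0.4), dab_od=np.zeros((16, 16)),
        residual_od=np.zeros((16, 16)), stain_matrix=metrics.DEFAULT_STAIN_MATRIX,
    )
    h = metrics.color_histogram(sep, bins=10)
    assert (h["hematoxylin"].raw_frequency > 0).sum() == 1
    with pytest.raises(ValueError):
        metrics.color_histogram(sep, bins=1)
    with pytest.raises(ValueError):
        metrics.color_histogram(sep, bandwidth=0.0)
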