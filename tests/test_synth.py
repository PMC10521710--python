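"""Synthetic tissue generator: grade phenotypes, rendering, and warps."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from virtualher2 import metrics, synth
from virtualher2.types import DeformationField, HER2Score, WarpSpec


def test_grade0_has_no_membrane(geom_small):
    latent = synth.generate_latent(0, geom_small, seed=7)
    assert latent.membrane_mask.sum() == 0
    assert latent.membrane_density.max() == 0.0


def test_grade3_complete_ring_fraction_exceeds_10_percent(geom_small):
    latent = synth.generate_latent(3, geom_small, seed=1)
    assert latent.n_cells > 0
    assert latent.complete_ring_fraction() >= 0.10


def test_latent_determinism(geom_small):
    a = synth.generate_latent(2, geom_small, seed=5)
    b = synth.generate_latent(2, geom_small, seed=5)
    np.testing.assert_array_equal(a.nucleus_labels, b.nucleus_labels)
    np.testing.assert_array_equal(a.membrane_density, b.membrane_density)


def test_pair_determinism_and_seed_sensitivity(geom_small):
    a = synth.simulate_pair(2, geom_small, seed=5)
    b = synth.simulate_pair(2, geom_small, seed=5)
    c = synth.simulate_pair(2, geom_small, seed=6)
    np.testing.assert_array_equal(a.af, b.af)
    np.testing.assert_array_equal(a.ihc, b.ihc)
    assert not np.array_equal(a.af, c.af)


def test_masks_disjoint_and_membrane_near_nuclei(geom_small):
    geom = geom_small
    latent = synth.generate_latent(3, geom, seed=3)
    assert not (latent.nucleus_mask & latent.membrane_mask).any()
    dist_to_nucleus = distance_transform_edt(~latent.nucleus_mask)
    max_dist = geom.membrane_gap + geom.membrane_thickness + 1.5
    assert dist_to_nucleus[latent.membrane_mask].max() <= max_dist


def test_empty_latent_renders_white():
    H = W = 64
    z = np.zeros((H, W))
    latent = synth.LatentTissueMap(
        nucleus_mask=z > 0, nucleus_labels=z.astype(np.int32), nucleus_density=z,
        membrane_mask=z > 0, membrane_density=z,
        complete_ring_flags=np.zeros(0, dtype=bool), stroma_field=z,
        height=H, width=W,
    )
    pair = synth.render_pair(latent, synth.OpticsParams(noise_sigma=0.0))
    assert pair.ihc.min() >= 0.99


def test_dapi_brighter_inside_nuclei(pair_grade2):
    latent = pair_grade2.latent
    dapi = pair_grade2.af[0]
    assert dapi[latent.nucleus_mask].mean() > dapi[~latent.nucleus_mask].mean()


def test_rendered_dab_concentrates_on_membrane(pair_grade3):
    sep = metrics.separate_stains(pair_grade3.ihc)
    mask = pair_grade3.latent.membrane_mask
    on = sep.dab_od[mask].mean()
    off = sep.dab_od[~mask].mean()
    assert on > 5 * max(off, 1e-9)


def test_grade_auc_monotone_on_rendered_tiles(geom_small):
    means = []
    for g in HER2Score:
        aucs = [
            metrics.membrane_stats(
                metrics.separate_stains(synth.simulate_pair(g, geom_small, seed=s).ihc)
            ).auc
            for s in range(4)
        ]
        means.append(np.mean(aucs))
    assert means[0] < means[1] < means[2] < means[3]


def test_af_channels_predict_nuclei_better_than_permuted(pair_grade2, rng):
    """The AF -> latent mapping is learnable: linear R^2 beats permuted channels."""
    y = pair_grade2.latent.nucleus_mask.ravel().astype(float)
    X = pair_grade2.af.reshape(4, -1).T
    Xp = np.column_stack([X, np.ones(len(X))])

    def r2(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return 1 - resid.var() / y.var()

    perm = rng.permutation(len(X))
    assert r2(Xp) > r2(np.column_stack([X[perm], np.ones(len(X))])) + 0.2


# -- warps ------------------------------------------------------------------


def test_make_warp_identity_and_translation():
    zero = synth.make_warp(WarpSpec(), (32, 32))
    assert np.abs(zero.dy).max() == 0 and np.abs(zero.dx).max() == 0
    spec = WarpSpec(affine=np.array([[1, 0, 12.0], [0, 1, -7.0]]))
    f = synth.make_warp(spec, (32, 32))
    assert np.allclose(f.dy, 12.0) and np.allclose(f.dx, -7.0)


def test_make_warp_elastic_magnitude_bound():
    spec = WarpSpec(elastic_amplitude=6.0, elastic_period=128.0, seed=2)
    f = synth.make_warp(spec, (256, 256))
    assert f.magnitude().max() <= 6.0 + 1e-9


def test_warpspec_validation():
    with pytest.raises(ValueError):
        WarpSpec(elastic_amplitude=-1.0)
    with pytest.raises(ValueError):
        WarpSpec(elastic_period=0.0)


def test_warp_image_zero_field_bit_identical(rng):
    img = rng.random((32, 32)).astype(np.float32)
    f = DeformationField(dy=np.zeros((32, 32)), dx=np.zeros((32, 32)))
    np.testing.assert_array_equal(synth.warp_image(img, f), img)


def test_warp_image_constant_preserved_interior():
    img = np.full((48, 48), 0.37)
    f = synth.make_warp(WarpSpec(elastic_amplitude=4, elastic_period=24, seed=1), (48, 48))
    out = synth.warp_image(img, f)
    np.testing.assert_allclose(out[6:-6, 6:-6], 0.37)


def test_warp_then_inverse_roundtrip(rng):
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.random((192, 192)), 2.0)  # band-limited test image
    f = synth.make_warp(
        WarpSpec(elastic_amplitude=5.0, elastic_period=96.0, seed=4), img.shape
    )
    warped = synth.warp_image(img, f)
    back = synth.warp_image(warped, synth.invert_field(f))
    err = np.abs(back - img)[10:-10, 10:-10].mean()
    assert err < 0.01


def test_warp_image_dimension_mismatch(rng):
    f = DeformationField(dy=np.zeros((16, 16)), dx=np.zeros((16, 16)))
    with pytest.raises(ValueError):
        synth.warp_image(rng.random((8, 8)), f)


def test_geometry_validation():
    with pytest.raises(ValueError):
        synth.GeometryParams(height=0)
    with pytest.raises(ValueError):
        synth.generate_latent("5+", seed=0)
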