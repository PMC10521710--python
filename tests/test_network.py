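"""Loss-function oracles and architecture conformance."""

import numpy as np
import pytest

from virtualher2.network import (
    DiscriminatorConfig,
    GeneratorConfig,
    LossWeights,
    bce_logits,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
    smooth_l1,
    ssim,
)
from virtualher2.nn import Tensor


# -- brute-force oracles ----------------------------------------------------


def brute_smooth_l1(a, b, beta):
    total = 0.0
    for d in np.abs(a - b).ravel():
        total += 0.5 * d * d / beta if d < beta else d - 0.5 * beta
    return total / a.size


def brute_ssim_global(a, b, c1, c2):
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = ((a - mu_a) ** 2).mean(), ((b - mu_b) ** 2).mean()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )


def brute_bce(p, q):
    s = 1.0 / (1.0 + np.exp(-np.asarray(p, dtype=float)))
    return float(np.mean(-q * np.log(s) - (1 - q) * np.log(1 - s)))


def test_loss_oracles_on_random_images(rng):
    for _ in range(30):
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        beta = float(rng.uniform(0.2, 2.0))
        assert abs(smooth_l1(a, b, beta) - brute_smooth_l1(a, b, beta)) < 1e-10
        assert abs(ssim(a, b) - brute_ssim_global(a, b, 1e-4, 9e-4)) < 1e-10
        p = rng.normal(0, 3, size=5)
        q = float(rng.integers(2))
        assert abs(bce_logits(p, q) - brute_bce(p, q)) < 1e-10


def test_loss_spot_values():
    a5 = np.full((4, 4), 0.5)
    z = np.zeros((4, 4))
    assert smooth_l1(a5, z, 1.0) == pytest.approx(0.125, abs=1e-12)
    assert smooth_l1(np.array([[2.0]]), np.array([[0.0]]), 1.0) == pytest.approx(1.5, abs=1e-12)
    assert smooth_l1(z, z) == 0.0
    assert ssim(np.zeros((8, 8)), np.zeros((8, 8))) == pytest.approx(1.0, abs=1e-12)
    assert ssim(np.zeros((8, 8)), np.ones((8, 8)), c1=1e-4) == pytest.approx(
        1e-4 / (1 + 1e-4), rel=1e-10
    )
    rnd = np.random.default_rng(0).random((8, 8))
    assert ssim(rnd, rnd) == pytest.approx(1.0, abs=1e-12)
    assert bce_logits(0.0, 1.0) == pytest.approx(np.log(2), abs=1e-12)
    assert bce_logits(100.0, 1.0) < 1e-10
    assert bce_logits(np.log(3.0), 1.0) == pytest.approx(-np.log(0.75), abs=1e-12)
    assert discriminator_loss(0.0, 0.0) == pytest.approx(2 * np.log(2), abs=1e-12)
    assert discriminator_loss(-100.0, 100.0) < 1e-10


def test_bce_numerically_stable_and_validates_labels():
    assert np.isfinite(bce_logits(1e4, 0.0))
    assert np.isfinite(bce_logits(-1e4, 1.0))
    with pytest.raises(ValueError):
        bce_logits(0.0, 0.5)


def test_generator_loss_components():
    t = np.random.default_rng(3).random((16, 16, 3))
    w = LossWeights()
    # perfect output, neutral discriminator: only gamma * ln 2 remains
    assert generator_loss(t, t, 0.0, w) == pytest.approx(0.5 * np.log(2), abs=1e-12)
    assert (w.alpha, w.lam, w.gamma) == (10.0, 0.2, 0.5)


def test_generator_loss_monotone_towards_target(rng):
    """Moving the output linearly toward the target lowers the loss."""
    target = rng.random((12, 12, 3))
    start = rng.random((12, 12, 3))
    w = LossWeights()
    losses = [
        generator_loss(start + alpha * (target - start), target, 0.0, w)
        for alpha in np.linspace(0, 1, 8)
    ]
    assert all(b < a + 1e-12 for a, b in zip(losses, losses[1:]))


def test_loss_weight_validation():
    with pytest.raises(ValueError):
        LossWeights(beta=0.0)
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)
    with pytest.raises(ValueError):
        smooth_l1(np.zeros((2, 2)), np.zeros((3, 3)))


def test_windowed_ssim_matches_skimage_convention(rng):
    a = rng.random((48, 48))
    b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
    from skimage.metrics import structural_similarity

    ref = structural_similarity(
        a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False,
    )
    assert ssim(a, b, mode="windowed") == pytest.approx(ref, abs=1e-12)


# -- architecture conformance ----------------------------------------------


def test_generator_channel_plan_matches_config():
    cfg = GeneratorConfig()
    gen = build_generator(cfg, seed=0)
    skip_chs = list(reversed(cfg.down_out))
    for i, block in enumerate(gen.down_blocks):
        assert block.conv1.in_channels == cfg.down_in[i]
        assert block.conv1.out_channels == cfg.down_out[i]
        assert block.conv2.out_channels == cfg.down_out[i]
    assert gen.center.conv1.in_channels == cfg.down_out[-1]
    assert gen.center.conv2.out_channels == cfg.up_in[0]
    for i, block in enumerate(gen.up_blocks):
        # nominal input (upsampled running tensor) + attention-gated skip
        assert block.conv1.in_channels == cfg.up_in[i] + skip_chs[i]
        assert block.conv1.out_channels == cfg.up_out[i]
    assert gen.final_conv.out_channels == 3
    assert cfg.down_in == (4, 64, 128, 256)
    assert cfg.down_out == (64, 128, 256, 512)
    assert cfg.up_in == (1024, 1024, 512, 256)
    assert cfg.up_out == (1024, 512, 256, 128)


def test_generator_is_fully_convolutional(rng):
    gen = build_generator(GeneratorConfig().reduced(16), seed=0)
    for size in (32, 64, 96):
        out = gen.infer(rng.random((4, size, size), dtype=np.float32))
        assert out.shape == (3, size, size)
    with pytest.raises(ValueError):
        gen.infer(rng.random((4, 40, 40), dtype=np.float32))  # not /16
    with pytest.raises(ValueError):
        gen(np.zeros((1, 32, 32, 3), dtype=np.float32))  # wrong channels


def test_attention_maps_bounded(rng):
    gen = build_generator(GeneratorConfig().reduced(16), seed=0)
    gen.infer(rng.random((4, 32, 32), dtype=np.float32))
    maps = gen.attention_maps()
    assert len(maps) == 4
    for m in maps:
        assert m.min() >= 0.0 and m.max() <= 1.0


def test_discriminator_plan_and_output(rng):
    cfg = DiscriminatorConfig()
    disc = build_discriminator(cfg, seed=0)
    assert disc.init_conv.out_channels == 64
    chans = [b.conv1.out_channels for b in disc.blocks]
    assert chans == [128, 256, 512, 1024, 2048]
    assert all(b.conv2.stride == 2 for b in disc.blocks)
    small = build_discriminator(cfg.reduced(8), seed=0)
    x = rng.random((2, 64, 64, 3), dtype=np.float32)
    out = small(x)
    assert out.data.shape == (2, 1)
    # five stride-2 blocks: spatial dims shrink 2^5
    assert 64 // 2**5 == 2


def test_seeded_models_reproducible(rng):
    x = rng.random((3, 32, 32), dtype=np.float32)
    af = np.random.default_rng(9).random((4, 32, 32), dtype=np.float32)
    g1 = build_generator(GeneratorConfig().reduced(16), seed=5)
    g2 = build_generator(GeneratorConfig().reduced(16), seed=5)
    d1 = build_discriminator(DiscriminatorConfig().reduced(16), seed=5)
    d2 = build_discriminator(DiscriminatorConfig().reduced(16), seed=5)
    np.testing.assert_array_equal(g1.infer(af), g2.infer(af))
    assert d1.infer(x) == d2.infer(x)
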