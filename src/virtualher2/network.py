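"""Generator/discriminator architectures and the composite GAN losses.

The generator is an attention-gated U-Net with four resolution levels
(channel plan 4, 64, 128, 256 -> 64, 128, 256, 512 on the way down and
1024, 1024, 512, 256 -> 1024, 512, 256, 128 on the way up); the
discriminator is a residual CNN with five 2x-downsampling blocks and two
fully connected layers ending in a single logit.  The generator objective is

    l_G = alpha * SmoothL1(target, output)
        - lambda * log((1 + SSIM(target, output)) / 2)
        + gamma * BCE(D(output), 1)

with (alpha, lambda, gamma) = (10, 0.2, 0.5), and the discriminator
minimizes BCE(D(output), 0) + BCE(D(target), 1).

The loss functions below accept plain numpy arrays (returning a float) or
autodiff ``Tensor`` objects (returning a scalar ``Tensor`` suitable for
``backward()``).  SSIM offers the global-statistics form used in the
training objective and a standard 11x11 Gaussian sliding-window mode
(sigma = 1.5) for evaluation reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

from .nn import Discriminator, GeneratorUNet, Tensor, as_tensor, where


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 4
    out_channels: int = 3
    levels: int = 4
    down_in: tuple = (4, 64, 128, 256)
    down_out: tuple = (64, 128, 256, 512)
    up_in: tuple = (1024, 1024, 512, 256)
    up_out: tuple = (1024, 512, 256, 128)
    conv_kernel: int = 3
    leaky_slope: float = 0.1

    def __post_init__(self):
        for name in ("down_in", "down_out", "up_in", "up_out"):
            if len(getattr(self, name)) != self.levels:
                raise ValueError(f"{name} must list {self.levels} levels")
        if self.down_in[0] != self.in_channels:
            raise ValueError("down_in[0] must equal in_channels")
        if self.out_channels != 3:
            raise ValueError("generator output must be 3-channel RGB")

    def reduced(self, factor: int = 8) -> "GeneratorConfig":
        """Desk-scale variant: every internal channel width divided by `factor`."""
        shrink = lambda t: tuple(max(c // factor, 1) for c in t)
        return replace(
            self,
            down_in=(self.in_channels,) + shrink(self.down_in[1:]),
            down_out=shrink(self.down_out),
            up_in=shrink(self.up_in),
            up_out=shrink(self.up_out),
        )


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 3
    init_channels: int = 64
    residual_blocks: int = 5
    fc_hidden: int = 512

    def reduced(self, factor: int = 8) -> "DiscriminatorConfig":
        return replace(
            self,
            init_channels=max(self.init_channels // factor, 1),
            fc_hidden=max(self.fc_hidden // factor, 1),
        )


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 10.0
    lam: float = 0.2
    gamma: float = 0.5
    beta: float = 1.0
    c1: float = 1e-4
    c2: float = 9e-4

    def __post_init__(self):
        if min(self.alpha, self.lam, self.gamma, self.c1, self.c2) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.beta <= 0:
            raise ValueError("smooth-L1 beta must be positive")


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def _prepare(a, b):
    ta, tb = as_tensor(a), as_tensor(b)
    if ta.data.shape != tb.data.shape:
        raise ValueError(f"shape mismatch: {ta.data.shape} vs {tb.data.shape}")
    wants_tensor = isinstance(a, Tensor) or isinstance(b, Tensor)
    return ta, tb, wants_tensor


def _ret(t: Tensor, wants_tensor: bool):
    return t if wants_tensor else float(t.data)


def smooth_l1(a, b, beta: float = 1.0):
    """Smooth L1 (Huber-style) distance, mean-reduced over all pixels.

    Quadratic 0.5 d^2 / beta for |d| < beta, linear |d| - beta/2 beyond.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    ta, tb, wt = _prepare(a, b)
    d = ta - tb
    ad = d.abs()
    loss = where(ad.data < beta, (d * d) * (0.5 / beta), ad - 0.5 * beta)
    return _ret(loss.mean(), wt)


def ssim(a, b, c1: float = 1e-4, c2: float = 9e-4, mode: str = "global"):
    """Structural similarity between two images.

    mode="global" uses single per-image (per-channel) statistics — the form
    entering the training objective; mode="windowed" is the conventional
    11x11 Gaussian sliding-window SSIM (sigma 1.5) used for reporting, which
    only accepts plain arrays.  Multi-channel inputs are averaged over
    channels; the data range is taken as 1.
    """
    if mode == "windowed":
        if isinstance(a, Tensor) or isinstance(b, Tensor):
            raise TypeError("windowed SSIM operates on plain arrays")
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError("shape mismatch")
        kwargs = dict(
            K1=np.sqrt(c1), K2=np.sqrt(c2), sigma=1.5, gaussian_weights=True,
            use_sample_covariance=False, data_range=1.0,
        )
        if a.ndim == 3:
            # channel-first or channel-last both reduce to a channel mean
            ch_axis = 0 if a.shape[0] in (1, 3, 4) and a.shape[0] < a.shape[-1] else -1
            return float(_skimage_ssim(a, b, channel_axis=ch_axis, **kwargs))
        return float(_skimage_ssim(a, b, **kwargs))
    if mode != "global":
        raise ValueError("mode must be 'global' or 'windowed'")

    ta, tb, wt = _prepare(a, b)
    # treat leading axes as batch/channel; statistics over the last two axes
    if ta.data.ndim >= 2:
        axes = (ta.data.ndim - 2, ta.data.ndim - 1)
    else:
        axes = (0,)
    mu_a = ta.mean(axis=axes, keepdims=True)
    mu_b = tb.mean(axis=axes, keepdims=True)
    da, db_ = ta - mu_a, tb - mu_b
    var_a = (da * da).mean(axis=axes, keepdims=True)
    var_b = (db_ * db_).mean(axis=axes, keepdims=True)
    cov = (da * db_).mean(axis=axes, keepdims=True)
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return _ret((num / den).mean(), wt)


def bce_logits(p, q):
    """Binary cross-entropy on logits, mean-reduced; stable for |p| ~ 1e4.

    Uses the log-sum-exp form max(p,0) - p q + log(1 + exp(-|p|)).
    """
    tp = as_tensor(p)
    qa = np.asarray(q, dtype=tp.data.dtype)
    if not np.all(np.isin(qa, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    wants_tensor = isinstance(p, Tensor)
    relu_p = tp.relu()
    softplus = (1.0 + (-tp.abs()).exp()).log()
    loss = relu_p - tp * qa + softplus
    return _ret(loss.mean(), wants_tensor)


def generator_loss(output, target, d_logit, w: LossWeights = LossWeights()):
    """Composite generator objective (smooth L1 + SSIM log-term + adversarial)."""
    l1 = smooth_l1(target, output, beta=w.beta)
    s = ssim(target, output, c1=w.c1, c2=w.c2, mode="global")
    adv = bce_logits(d_logit, 1.0)
    if isinstance(l1, Tensor) or isinstance(s, Tensor) or isinstance(adv, Tensor):
        s = as_tensor(s)
        return w.alpha * as_tensor(l1) - w.lam * ((1.0 + s) * 0.5).log() + w.gamma * as_tensor(adv)
    return w.alpha * l1 - w.lam * np.log((1.0 + s) / 2.0) + w.gamma * adv


def discriminator_loss(d_logit_fake, d_logit_real):
    """BCE(fake, 0) + BCE(real, 1)."""
    return bce_logits(d_logit_fake, 0.0) + bce_logits(d_logit_real, 1.0)


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------


def build_generator(cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> GeneratorUNet:
    """Instantiate the attention U-Net generator with seeded He-normal init."""
    return GeneratorUNet(cfg, seed=seed)


def build_discriminator(cfg: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0) -> Discriminator:
    """Instantiate the residual CNN discriminator with seeded He-normal init."""
    return Discriminator(cfg, seed=seed)
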