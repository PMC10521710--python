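"""Network building blocks: convolutional modules with seeded He-normal init.

All modules operate on channel-last (B, H, W, C) float32 tensors; the
networks expose ``infer`` helpers accepting conventional channel-first
single images.  Parameters live in
``Tensor`` leaves with ``requires_grad=True``; ``Module.parameters()`` walks
attributes recursively so optimizers and checkpoints see every weight.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2d, upsample_bilinear2x

DTYPE = np.float32


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                seen.add(id(v))
                params.append(v)
            elif isinstance(v, Module):
                v._collect(params, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(params, seen)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = arr.copy()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = k // 2
        self.stride, self.pad = stride, pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, (k, k, cin, cout)).astype(DTYPE), True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), True) if bias else None

    @property
    def in_channels(self):
        return self.w.data.shape[2]

    @property
    def out_channels(self):
        return self.w.data.shape[3]

    def forward(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.w = Tensor(rng.normal(0.0, std, (cin, cout)).astype(DTYPE), True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), True)

    def forward(self, x):
        return x @ self.w + self.b


class ResConvBlock(Module):
    """Two 3x3 convolutions with a 1x1 convolutional residual path.

    The optional stride (applied to the second convolution and the residual
    path) implements the discriminator's in-block 2x downsampling.
    """

    def __init__(self, cin, cout, slope=0.1, stride=1, rng=None):
        self.slope = slope
        self.conv1 = Conv2d(cin, cout, 3, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, stride=stride, rng=rng)
        self.res = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)

    def forward(self, x):
        h = self.conv1(x).leaky_relu(self.slope)
        h = self.conv2(h)
        return h + self.res(x)


class AttentionGate(Module):
    """Additive attention gate: three convolutions and a sigmoid.

    1x1 convolutions project the skip tensor and the gating signal to an
    intermediate width, their sum passes through ReLU and a final 1x1
    convolution to one channel; the sigmoid of that map multiplicatively
    gates the skip tensor.
    """

    def __init__(self, skip_ch, gate_ch, rng=None):
        inter = max(skip_ch // 2, 1)
        self.w_skip = Conv2d(skip_ch, inter, 1, pad=0, bias=False, rng=rng)
        self.w_gate = Conv2d(gate_ch, inter, 1, pad=0, rng=rng)
        self.psi = Conv2d(inter, 1, 1, pad=0, rng=rng)
        self.last_map: np.ndarray | None = None

    def forward(self, skip, gate):
        a = (self.w_skip(skip) + self.w_gate(gate)).relu()
        weight = self.psi(a).sigmoid()
        self.last_map = weight.data
        return skip * weight


class GeneratorUNet(Module):
    """Attention-gated U-Net mapping 4-channel AF stacks to RGB brightfield.

    Wiring (cfg lists give the nominal per-level in/out channels):
      * four down blocks: residual conv block -> LeakyReLU(slope) -> skip ->
        2x2 max pool;
      * center residual block: down_out[-1] -> up_in[0];
      * four up blocks: bilinear 2x upsample of the running tensor
        (up_in[i] channels), attention-gated skip concatenated, residual
        conv block reducing up_in[i] + skip_ch -> up_out[i];
      * final residual block at up_out[-1] plus a single 3x3 convolution to
        out_channels.  Output is linear (no activation).
    """

    def __init__(self, cfg, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        s = cfg.leaky_slope
        self.slope = s
        self.down_blocks = [
            ResConvBlock(cfg.down_in[i], cfg.down_out[i], s, rng=rng)
            for i in range(cfg.levels)
        ]
        self.center = ResConvBlock(cfg.down_out[-1], cfg.up_in[0], s, rng=rng)
        skip_chs = list(reversed(cfg.down_out))
        self.gates = [
            AttentionGate(skip_chs[i], cfg.up_in[i], rng=rng) for i in range(cfg.levels)
        ]
        self.up_blocks = [
            ResConvBlock(cfg.up_in[i] + skip_chs[i], cfg.up_out[i], s, rng=rng)
            for i in range(cfg.levels)
        ]
        self.final_block = ResConvBlock(cfg.up_out[-1], cfg.up_out[-1], s, rng=rng)
        self.final_conv = Conv2d(cfg.up_out[-1], cfg.out_channels, 3, rng=rng)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        if x.data.ndim != 4 or x.data.shape[3] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.cfg.in_channels}) input, got {x.data.shape}"
            )
        H, W = x.data.shape[1:3]
        div = 2 ** self.cfg.levels
        if H % div or W % div:
            raise ValueError(f"spatial dims must be divisible by {div}")
        skips = []
        for block in self.down_blocks:
            x = block(x).leaky_relu(self.slope)
            skips.append(x)
            x = maxpool2d(x)
        x = self.center(x).leaky_relu(self.slope)
        for i, block in enumerate(self.up_blocks):
            x = upsample_bilinear2x(x)
            gated = self.gates[i](skips[-1 - i], x)
            x = block(concat([x, gated], axis=-1)).leaky_relu(self.slope)
        x = self.final_block(x).leaky_relu(self.slope)
        return self.final_conv(x)

    def infer(self, af_stack: np.ndarray) -> np.ndarray:
        """Virtually stain one channel-first AF stack (C, H, W) -> (C_out, H, W)."""
        from .autograd import no_grad

        af_stack = np.asarray(af_stack, dtype=DTYPE)
        if af_stack.ndim != 3:
            raise ValueError("expected a single (C, H, W) stack")
        with no_grad():
            out = self.forward(af_stack.transpose(1, 2, 0)[None])
        return out.data[0].transpose(2, 0, 1)

    def attention_maps(self) -> list[np.ndarray]:
        return [g.last_map for g in self.gates]


class Discriminator(Module):
    """Residual CNN classifier producing one real-vs-virtual logit.

    Initial 3x3 convolution + LeakyReLU to ``init_channels``; five residual
    blocks each doubling channels and halving the spatial dimensions (stride
    2 on the block's second convolution); global average pooling; two fully
    connected layers to a single logit.
    """

    def __init__(self, cfg, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.slope = 0.1
        self.init_conv = Conv2d(cfg.in_channels, cfg.init_channels, 3, rng=rng)
        self.blocks = []
        c = cfg.init_channels
        for _ in range(cfg.residual_blocks):
            self.blocks.append(ResConvBlock(c, 2 * c, self.slope, stride=2, rng=rng))
            c *= 2
        self.fc1 = Linear(c, cfg.fc_hidden, rng=rng)
        self.fc2 = Linear(cfg.fc_hidden, 1, rng=rng)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        if x.data.shape[3] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels}-channel input")
        x = self.init_conv(x).leaky_relu(self.slope)
        for block in self.blocks:
            x = block(x).leaky_relu(self.slope)
        x = x.mean(axis=(1, 2))
        x = self.fc1(x).leaky_relu(self.slope)
        return self.fc2(x)

    def infer(self, rgb: np.ndarray) -> float:
        """Logit for a single channel-first (3, H, W) image."""
        from .autograd import no_grad

        rgb = np.asarray(rgb, dtype=DTYPE)
        with no_grad():
            out = self.forward(rgb.transpose(1, 2, 0)[None])
        return float(out.data.ravel()[0])
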