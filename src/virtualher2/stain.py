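"""Tile-wise virtual staining inference and seamless WSI reassembly.

Only the trained generator is used at inference time.  The WSI is covered
by overlapping tiles; each tile is stained independently and the results
are blended with cosine feathering in the overlap regions (per-pixel blend
weights are normalized to sum to one), avoiding edge artifacts from
convolutional padding effects.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileGrid:
    tile_size: int
    overlap: int
    origins: tuple  # ((row, col), ...)
    wsi_shape: tuple

    @classmethod
    def regular(cls, wsi_shape: tuple, tile_size: int = 512, overlap: int = 64):
        """Grid covering the WSI; the last row/column is aligned to the edge."""
        H, W = wsi_shape
        if tile_size > H or tile_size > W:
            raise ValueError("tile_size exceeds WSI dimensions")
        if not 0 <= overlap < tile_size:
            raise ValueError("overlap must lie in [0, tile_size)")
        step = tile_size - overlap

        def _starts(n):
            s = list(range(0, n - tile_size + 1, step))
            if s[-1] != n - tile_size:
                s.append(n - tile_size)
            return s

        origins = tuple((r, c) for r in _starts(H) for c in _starts(W))
        return cls(tile_size=tile_size, overlap=overlap, origins=origins,
                   wsi_shape=(H, W))


@dataclass(frozen=True)
class StitchConfig:
    blend: str = "feather"  # "feather" (cosine ramp) or "average"
    overlap: int = 64
    output_range: tuple = (0.0, 1.0)

    def __post_init__(self):
        if self.blend not in ("feather", "average"):
            raise ValueError("blend must be 'feather' or 'average'")


def _feather_profile(n: int, ramp: int) -> np.ndarray:
    """1-D weight profile: cosine ramps of width `ramp` at both ends."""
    w = np.ones(n)
    if ramp > 0:
        t = (np.arange(ramp) + 0.5) / ramp
        edge = 0.5 * (1.0 - np.cos(np.pi * t))
        w[:ramp] = edge
        w[n - ramp :] = edge[::-1]
    return w


def tile_weight(tile_size: int, overlap: int, blend: str) -> np.ndarray:
    if blend == "average":
        return np.ones((tile_size, tile_size))
    p = _feather_profile(tile_size, overlap)
    return np.outer(p, p)


def stain_wsi(
    af_wsi: np.ndarray,
    model,
    grid: TileGrid | None = None,
    stitch: StitchConfig | None = None,
    normalizer=None,
) -> np.ndarray:
    """Virtually stain a (4, H, W) AF WSI into an (H, W, 3) brightfield image.

    `model` is either a callable mapping a (4, h, w) tile to an (h, w, 3)
    or (3, h, w) tile, or an object exposing such an ``infer`` method (the
    trained generator).  `normalizer` (optional) is applied to each AF tile
    before inference — it should be the normalizer stored with the
    checkpoint so training and inference see identical statistics.
    """
    af_wsi = np.asarray(af_wsi)
    if af_wsi.ndim != 3 or af_wsi.shape[0] != 4:
        raise ValueError("expected a (4, H, W) autofluorescence stack")
    H, W = af_wsi.shape[1:]
    stitch = stitch or StitchConfig()
    grid = grid or TileGrid.regular((H, W), overlap=stitch.overlap)
    infer = model.infer if hasattr(model, "infer") else model

    out = np.zeros((H, W, 3))
    weight = np.zeros((H, W))
    w_tile = tile_weight(grid.tile_size, grid.overlap, stitch.blend)
    t0 = time.perf_counter()
    for r, c in grid.origins:
        tile = af_wsi[:, r : r + grid.tile_size, c : c + grid.tile_size]
        if normalizer is not None:
            tile = normalizer(tile)
        pred = np.asarray(infer(tile))
        if pred.ndim != 3:
            raise ValueError("model output must be a 3-channel image")
        if pred.shape[0] == 3 and pred.shape[-1] != 3:
            pred = pred.transpose(1, 2, 0)
        if pred.shape[:2] != (grid.tile_size, grid.tile_size):
            raise ValueError("model changed the tile size")
        out[r : r + grid.tile_size, c : c + grid.tile_size] += pred * w_tile[..., None]
        weight[r : r + grid.tile_size, c : c + grid.tile_size] += w_tile
    out /= weight[..., None]
    elapsed = time.perf_counter() - t0
    log.info(
        "stained %dx%d WSI in %.2f s (%.2f Mpx/s, %d tiles)",
        H, W, elapsed, H * W / max(elapsed, 1e-9) / 1e6, len(grid.origins),
    )
    lo, hi = stitch.output_range
    return np.clip(out, lo, hi)
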