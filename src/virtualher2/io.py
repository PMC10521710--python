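"""Image and table I/O helpers.

AF stacks travel as multi-page TIFF (channel order DAPI, FITC, TxRed, Cy5
recorded in metadata); brightfield images as RGB TIFF/PNG.  All images are
normalized to float [0, 1] in memory with 0-based (row, col) coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

AF_CHANNELS = ("DAPI", "FITC", "TxRed", "Cy5")


def read_af_stack(path) -> np.ndarray:
    """Read a (4, H, W) autofluorescence stack from a multi-page TIFF."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError("expected a multi-channel AF stack")
    if arr.ndim == 3 and arr.shape[-1] == 4 and arr.shape[0] != 4:
        arr = arr.transpose(2, 0, 1)
    if arr.shape[0] != 4:
        raise ValueError(f"expected 4 AF channels, found shape {arr.shape}")
    return _to_unit(arr)


def write_af_stack(path, af: np.ndarray) -> None:
    af = np.asarray(af)
    if af.ndim != 3 or af.shape[0] != 4:
        raise ValueError("expected a (4, H, W) stack")
    tifffile.imwrite(
        path,
        (np.clip(af, 0, 1) * 65535).astype(np.uint16),
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": ",".join(AF_CHANNELS)},
    )


def read_rgb(path) -> np.ndarray:
    """Read an (H, W, 3) brightfield image as float in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return _to_unit(arr[..., :3])


def write_rgb(path, rgb: np.ndarray) -> None:
    rgb8 = (np.clip(np.asarray(rgb), 0, 1) * 255).round().astype(np.uint8)
    iio.imwrite(path, rgb8)


def _to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


class _MetricsEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_metrics_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_MetricsEncoder))
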