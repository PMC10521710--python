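"""Feature-based quantitative assessment of HER2 brightfield images.

Color deconvolution splits an RGB brightfield tile into hematoxylin
(nucleus) and DAB (membrane) optical-density channels under the
Beer-Lambert model.  From these the module derives:

* nucleus statistics — Otsu threshold on the hematoxylin channel,
  morphological opening, small-object removal, connected-region count and
  mean area;
* the membrane characteristic curve — the DAB channel is re-rendered to
  RGB, converted to HSV, and the stained-area fraction is swept over a
  saturation threshold s = 0.10 ... 0.50 (step 0.02); its trapezoidal AUC
  and the largest-component fraction at s = 0.25 ("membrane region
  connectedness") summarize membrane stain expression;
* image-quality metrics — PSNR, windowed SSIM, and SSIM restricted to the
  deconvolved DAB channel (SSIM_DAB);
* per-stain color histograms with Gaussian kernel smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening

from .network import ssim as _ssim
from .types import DegenerateThresholdError

# Standard hematoxylin / DAB optical-density unit vectors; the third row is
# the normalized cross product completing an invertible stain basis.
_H = np.array([0.650, 0.704, 0.286])
_D = np.array([0.269, 0.568, 0.778])


def _unit(v):
    return v / np.linalg.norm(v)


def default_stain_matrix() -> np.ndarray:
    h, d = _unit(_H), _unit(_D)
    r = _unit(np.cross(h, d))
    return np.stack([h, d, r])


DEFAULT_STAIN_MATRIX = default_stain_matrix()


@dataclass
class StainSeparation:
    hematoxylin_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray
    stain_matrix: np.ndarray


@dataclass
class NucleusStats:
    count: int
    mean_area: float
    segmentation: np.ndarray


@dataclass
class CharacteristicCurve:
    s_values: np.ndarray
    area_ratio: np.ndarray
    auc: float
    connectedness: float


@dataclass
class QualityMetrics:
    psnr: float
    ssim: float
    ssim_dab: float


@dataclass
class ColorHistogram:
    bin_centers: np.ndarray
    raw_frequency: np.ndarray
    smoothed_profile: np.ndarray


def beer_lambert_rgb(
    hema_od: np.ndarray,
    dab_od: np.ndarray,
    stain_matrix: np.ndarray = DEFAULT_STAIN_MATRIX,
) -> np.ndarray:
    """Render per-pixel stain densities to RGB transmission (white = no stain)."""
    hema_od = np.asarray(hema_od, dtype=float)
    dab_od = np.asarray(dab_od, dtype=float)
    if np.any(hema_od < 0) or np.any(dab_od < 0):
        raise ValueError("optical densities must be non-negative")
    od = (
        hema_od[..., None] * stain_matrix[0] + dab_od[..., None] * stain_matrix[1]
    )
    return np.power(10.0, -od)


def separate_stains(
    rgb: np.ndarray,
    stain_matrix: np.ndarray = DEFAULT_STAIN_MATRIX,
    eps: float = 1e-6,
) -> StainSeparation:
    """Color deconvolution of an (H, W, 3) brightfield tile in [0, 1].

    OD = -log10(max(rgb, eps)); per-pixel densities = OD @ inv(matrix);
    negative densities are clipped to zero.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    stain_matrix = np.asarray(stain_matrix, dtype=float)
    if abs(np.linalg.det(stain_matrix)) < 1e-8:
        raise ValueError("stain matrix is singular")
    od = -np.log10(np.maximum(rgb, eps))
    dens = od @ np.linalg.inv(stain_matrix)
    dens = np.clip(dens, 0.0, None)
    return StainSeparation(
        hematoxylin_od=dens[..., 0],
        dab_od=dens[..., 1],
        residual_od=dens[..., 2],
        stain_matrix=stain_matrix,
    )


def nucleus_stats(
    sep: StainSeparation,
    opening_radius: int = 2,
    min_area: int = 30,
    connectivity: int = 2,
) -> NucleusStats:
    """Count nuclei and mean nucleus area from the hematoxylin channel."""
    hema = sep.hematoxylin_od
    if np.ptp(hema) == 0:
        raise DegenerateThresholdError(
            "hematoxylin channel is constant; Otsu threshold undefined"
        )
    thr = threshold_otsu(hema)
    mask = hema > thr
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    labels = cc_label(mask, connectivity=connectivity)
    if min_area > 0 and labels.max():
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_area
        keep[0] = False
        mask = keep[labels]
        labels = cc_label(mask, connectivity=connectivity)
    count = int(labels.max())
    mean_area = float(mask.sum() / count) if count else 0.0
    return NucleusStats(count=count, mean_area=mean_area, segmentation=labels)


def characteristic_curve_from_saturation(
    saturation: np.ndarray,
    s_grid: np.ndarray | None = None,
    s_conn: float = 0.25,
    connectivity: int = 2,
) -> CharacteristicCurve:
    """Characteristic curve of a saturation image: stained-area fraction vs s."""
    if s_grid is None:
        s_grid = np.round(np.arange(0.10, 0.50 + 1e-9, 0.02), 4)
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((s_grid <= 0) | (s_grid >= 1)) or not (0 < s_conn < 1):
        raise ValueError("saturation thresholds must lie in (0, 1)")
    sat = np.asarray(saturation, dtype=float)
    fov = sat.size
    area_ratio = np.array([(sat > s).mean() for s in s_grid])
    auc = float(np.trapezoid(area_ratio, s_grid))
    conn_mask = sat > s_conn
    if conn_mask.any():
        labels = cc_label(conn_mask, connectivity=connectivity)
        largest = np.bincount(labels.ravel())[1:].max()
        connectedness = float(largest / fov)
    else:
        connectedness = 0.0
    return CharacteristicCurve(
        s_values=s_grid, area_ratio=area_ratio, auc=auc, connectedness=connectedness
    )


def membrane_stats(
    sep: StainSeparation,
    s_grid: np.ndarray | None = None,
    s_conn: float = 0.25,
    connectivity: int = 2,
) -> CharacteristicCurve:
    """Membrane characteristic curve, AUC and connectedness of a tile.

    The DAB density is re-rendered to RGB on its own (hematoxylin zeroed),
    converted to HSV, and the saturation channel is thresholded.
    """
    dab_rgb = beer_lambert_rgb(
        np.zeros_like(sep.dab_od), sep.dab_od, sep.stain_matrix
    )
    sat = rgb2hsv(np.clip(dab_rgb, 0.0, 1.0))[..., 1]
    return characteristic_curve_from_saturation(sat, s_grid, s_conn, connectivity)


def image_quality(
    virtual: np.ndarray,
    target: np.ndarray,
    stain_matrix: np.ndarray = DEFAULT_STAIN_MATRIX,
    psnr_cap: float = 100.0,
) -> QualityMetrics:
    """PSNR, windowed SSIM and DAB-channel SSIM between paired tiles in [0, 1]."""
    virtual = np.asarray(virtual, dtype=float)
    target = np.asarray(target, dtype=float)
    if virtual.shape != target.shape:
        raise ValueError("image shapes differ")
    mse = float(np.mean((virtual - target) ** 2))
    psnr = psnr_cap if mse == 0 else min(10.0 * np.log10(1.0 / mse), psnr_cap)
    s = _ssim(virtual, target, mode="windowed")
    dab_v = separate_stains(virtual, stain_matrix).dab_od
    dab_t = separate_stains(target, stain_matrix).dab_od
    s_dab = _ssim(dab_v, dab_t, mode="windowed")
    return QualityMetrics(psnr=float(psnr), ssim=s, ssim_dab=s_dab)


def color_histogram(
    sep: StainSeparation, bins: int = 64, bandwidth: float = 0.05
) -> dict[str, ColorHistogram]:
    """Normalized per-stain histograms with Gaussian kernel smoothing.

    `bandwidth` is in optical-density units; raw frequencies are normalized
    by the total pixel count, and the reflected-boundary smoothing keeps the
    profile mass equal to 1.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    out = {}
    for name, chan in (("hematoxylin", sep.hematoxylin_od), ("dab", sep.dab_od)):
        vmax = max(float(chan.max()), 1e-9)
        counts, edges = np.histogram(chan.ravel(), bins=bins, range=(0.0, vmax))
        freq = counts / chan.size
        sigma_bins = min(bandwidth / (edges[1] - edges[0]), float(bins))
        smoothed = gaussian_filter1d(freq, sigma=sigma_bins, mode="reflect")
        out[name] = ColorHistogram(
            bin_centers=0.5 * (edges[:-1] + edges[1:]),
            raw_frequency=freq,
            smoothed_profile=smoothed,
        )
    return out
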