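"""Seeded synthetic paired-tile generator.

Emulates the study conditions of a label-free virtual HER2 staining
experiment on breast tissue: a latent tissue map (nuclei, membrane rings,
stroma) is drawn per tile, then rendered twice —

* a 4-channel autofluorescence stack (DAPI, FITC, TxRed, Cy5 analogues),
  each channel a fixed nonlinear mix of the latent maps plus Gaussian
  sensor noise, and
* an RGB brightfield IHC image via Beer-Lambert transmission from
  hematoxylin (nuclei) and DAB (membrane) optical densities.

The per-grade membrane model follows the HercepTest phenotype ladder:
grade 0 has no membrane stain; 1+ faint partial rings; 2+ weak-to-moderate
complete rings in more than 10% of tumor cells; 3+ strong complete rings in
more than 10% of cells.  Ring counts are assigned deterministically
(rounded fractions of the cell count), so the >10% properties hold by
construction, not just in expectation.

Known parametric warps (affine + sinusoidal elastic) and a pull-back image
warper provide ground truth for registration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .metrics import DEFAULT_STAIN_MATRIX, beer_lambert_rgb
from .types import (
    DeformationField,
    HER2Score,
    LatentTissueMap,
    SyntheticPair,
    WarpSpec,
)


@dataclass(frozen=True)
class GradeMembraneParams:
    """Membrane phenotype knobs for one HER2 grade."""

    complete_fraction: float  # fraction of cells with complete rings
    partial_fraction: float  # fraction with partial rings
    completeness_range: tuple  # arc fraction drawn for partial rings
    dab_density: float  # mean DAB optical density on stained membrane


#: Per-grade phenotype ladder (0, 1+, 2+, 3+).
GRADE_MEMBRANE: dict[HER2Score, GradeMembraneParams] = {
    HER2Score.ZERO: GradeMembraneParams(0.0, 0.0, (0.0, 0.0), 0.0),
    HER2Score.ONE: GradeMembraneParams(0.0, 0.45, (0.15, 0.50), 0.15),
    HER2Score.TWO: GradeMembraneParams(0.35, 0.20, (0.50, 0.90), 0.35),
    HER2Score.THREE: GradeMembraneParams(0.60, 0.15, (0.50, 0.90), 0.90),
}


@dataclass(frozen=True)
class GeometryParams:
    height: int = 256
    width: int = 256
    cell_density: float = 0.0022  # cells per pixel^2
    min_spacing: float = 17.0  # minimum center-to-center distance, px
    nucleus_radius: tuple = (4.0, 7.0)
    membrane_gap: float = 1.0  # annulus gap between nucleus and ring, px
    membrane_thickness: float = 2.0  # ring thickness, px
    nucleus_density_range: tuple = (0.55, 0.80)  # hematoxylin OD per cell
    stroma_smoothness: float = 8.0  # Gaussian sigma of the stroma field, px

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("tile dimensions must be positive")


@dataclass(frozen=True)
class OpticsParams:
    """Rendering model: AF channel mixing weights and stain intensities.

    Each AF channel is ``clip(gamma(w_nuc * nuc + w_mem * mem + w_str *
    stroma) + noise)`` where nuc/mem are the latent optical-density maps
    (so stain strength is encoded in the AF signal) and gamma is a mild
    power-law saturation.
    """

    # per-channel weights: (nucleus, membrane, stroma) for DAPI/FITC/TxRed/Cy5
    af_weights: tuple = (
        (1.10, 0.00, 0.10),
        (0.30, 0.15, 0.55),
        (0.08, 0.65, 0.25),
        (0.12, 0.35, 0.35),
    )
    af_gamma: float = 0.8
    noise_sigma: float = 0.02
    poisson_noise: bool = False
    stroma_hema_od: float = 0.06  # faint hematoxylin pickup in stroma
    stain_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.copy()
    )

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _place_cells(rng, geom: GeometryParams) -> np.ndarray:
    """Dart-throwing cell centers with a minimum spacing; (n, 2) rows/cols."""
    target = int(round(geom.cell_density * geom.height * geom.width))
    margin = geom.nucleus_radius[1] + geom.membrane_gap + geom.membrane_thickness
    centers: list = []
    attempts = 0
    while len(centers) < target and attempts < 60 * target:
        attempts += 1
        p = rng.uniform(
            (margin, margin), (geom.height - margin, geom.width - margin)
        )
        if all(np.hypot(*(p - q)) >= geom.min_spacing for q in centers):
            centers.append(p)
    return np.array(centers) if centers else np.empty((0, 2))


def generate_latent(
    grade,
    geometry: GeometryParams | None = None,
    seed: int = 0,
) -> LatentTissueMap:
    """Draw the latent tissue map for one tile at the given HER2 grade."""
    grade = HER2Score.from_label(grade)
    geom = geometry or GeometryParams()
    rng = np.random.default_rng(seed)
    H, W = geom.height, geom.width
    mem = GRADE_MEMBRANE[grade]

    centers = _place_cells(rng, geom)
    n = len(centers)
    radii = rng.uniform(*geom.nucleus_radius, size=n)
    nuc_od_per_cell = rng.uniform(*geom.nucleus_density_range, size=n)

    rr, cc = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.int32)
    nucleus_density = np.zeros((H, W))
    membrane_mask = np.zeros((H, W), dtype=bool)
    membrane_density = np.zeros((H, W))

    # ring assignment: deterministic counts, shuffled cell order
    order = rng.permutation(n)
    n_complete = int(round(mem.complete_fraction * n))
    n_partial = int(round(mem.partial_fraction * n))
    complete_ids = set(order[:n_complete].tolist())
    partial_ids = set(order[n_complete : n_complete + n_partial].tolist())
    complete_flags = np.zeros(n, dtype=bool)

    for i, (cy, cx) in enumerate(centers):
        r = radii[i]
        box = (slice(max(int(cy - r - 12), 0), min(int(cy + r + 13), H)),
               slice(max(int(cx - r - 12), 0), min(int(cx + r + 13), W)))
        dy = rr[box] - cy
        dx = cc[box] - cx
        dist = np.hypot(dy, dx)
        ndisk = dist <= r
        labels[box][ndisk] = i + 1
        nucleus_density[box][ndisk] = nuc_od_per_cell[i]

        stained = i in complete_ids or i in partial_ids
        if not stained or mem.dab_density == 0:
            continue
        r_in = r + geom.membrane_gap
        r_out = r_in + geom.membrane_thickness
        ring = (dist >= r_in) & (dist <= r_out)
        if i in complete_ids:
            completeness = 1.0
            complete_flags[i] = True
        else:
            completeness = rng.uniform(*mem.completeness_range)
            theta = np.arctan2(dy, dx)
            start = rng.uniform(-np.pi, np.pi)
            span = completeness * 2 * np.pi
            rel = np.mod(theta - start, 2 * np.pi)
            ring &= rel <= span
        density = mem.dab_density * rng.uniform(0.8, 1.2)
        membrane_mask[box] |= ring
        membrane_density[box][ring] = density

    stroma = gaussian_filter(rng.random((H, W)), geom.stroma_smoothness)
    lo, hi = stroma.min(), stroma.max()
    stroma = (stroma - lo) / (hi - lo) if hi > lo else np.zeros((H, W))

    return LatentTissueMap(
        nucleus_mask=labels > 0,
        nucleus_labels=labels,
        nucleus_density=nucleus_density,
        membrane_mask=membrane_mask,
        membrane_density=membrane_density,
        complete_ring_flags=complete_flags,
        stroma_field=stroma,
        height=H,
        width=W,
    )


def render_pair(
    latent: LatentTissueMap,
    optics: OpticsParams | None = None,
    grade=HER2Score.ZERO,
    seed: int = 0,
) -> SyntheticPair:
    """Render the AF stack and IHC brightfield image for a latent map."""
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)
    H, W = latent.height, latent.width
    if latent.nucleus_density.shape != (H, W):
        raise ValueError("latent map dimensions are inconsistent")

    hema_od = latent.nucleus_density + optics.stroma_hema_od * latent.stroma_field
    dab_od = latent.membrane_density
    ihc = beer_lambert_rgb(hema_od, dab_od, optics.stain_matrix).astype(np.float32)

    af = np.empty((4, H, W), dtype=np.float32)
    for ch, (w_nuc, w_mem, w_str) in enumerate(optics.af_weights):
        signal = (
            w_nuc * latent.nucleus_density
            + w_mem * latent.membrane_density
            + w_str * 0.5 * latent.stroma_field
        )
        signal = np.power(np.clip(signal, 0.0, None), optics.af_gamma)
        if optics.poisson_noise:
            signal = rng.poisson(np.clip(signal, 0, None) * 400.0) / 400.0
        signal = signal + rng.normal(0.0, optics.noise_sigma, (H, W))
        af[ch] = np.clip(signal, 0.0, 1.0)

    return SyntheticPair(
        af=af,
        ihc=np.clip(ihc, 0.0, 1.0),
        latent=latent,
        grade=HER2Score.from_label(grade),
        seed=seed,
    )


def simulate_pair(
    grade,
    geometry: GeometryParams | None = None,
    optics: OpticsParams | None = None,
    seed: int = 0,
) -> SyntheticPair:
    """Generate one fully seeded synthetic AF/IHC pair at the given grade."""
    grade = HER2Score.from_label(grade)
    latent = generate_latent(grade, geometry, seed=seed)
    # decorrelate the sensor-noise stream from the geometry stream
    pair = render_pair(latent, optics, grade=grade, seed=seed + 1_000_003)
    pair.seed = seed
    return pair


def simulate_dataset(
    n_per_grade: int,
    grades=tuple(HER2Score),
    geometry: GeometryParams | None = None,
    optics: OpticsParams | None = None,
    tiles_per_patient: int = 4,
    base_seed: int = 0,
) -> list[SyntheticPair]:
    """A grade-mixed tile collection; seeds encode a patient structure.

    Consecutive ``tiles_per_patient`` tiles of one grade share a synthetic
    patient; the pair seed is derived from (base_seed, grade, index).
    """
    pairs = []
    for grade in grades:
        grade = HER2Score.from_label(grade)
        for i in range(n_per_grade):
            seed = base_seed + 10_000 * int(grade) + i
            pair = simulate_pair(grade, geometry, optics, seed=seed)
            pairs.append(pair)
    return pairs


def patient_id_for(pair: SyntheticPair, tiles_per_patient: int = 4) -> str:
    """Synthetic patient identifier implied by the dataset seed layout."""
    idx = pair.seed % 10_000
    return f"G{int(pair.grade)}P{idx // tiles_per_patient:03d}"


# --------------------------------------------------------------------------
# warps
# --------------------------------------------------------------------------


def make_warp(spec: WarpSpec, shape: tuple) -> DeformationField:
    """Dense pull-back displacement field for a parametric warp.

    The affine part contributes ``A @ (r, c, 1) - (r, c)``; the elastic part
    adds sinusoids of the given amplitude and period (each component scaled
    by 1/sqrt(2) so the elastic displacement magnitude never exceeds the
    amplitude).
    """
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    A = spec.affine
    dy = A[0, 0] * rr + A[0, 1] * cc + A[0, 2] - rr
    dx = A[1, 0] * rr + A[1, 1] * cc + A[1, 2] - cc
    if spec.elastic_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        amp = spec.elastic_amplitude / np.sqrt(2.0)
        dy = dy + amp * np.sin(2 * np.pi * cc / spec.elastic_period + ph1)
        dx = dx + amp * np.sin(2 * np.pi * rr / spec.elastic_period + ph2)
    return DeformationField(dy=dy, dx=dx)


_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}
_MODE = {"edge": "nearest", "reflect": "reflect", "constant": "constant"}


def warp_image(
    image: np.ndarray,
    f: DeformationField,
    interpolation: str = "linear",
    fill: str = "edge",
    cval: float = 0.0,
) -> np.ndarray:
    """Resample `image` along the pull-back field: out(r,c) = img(r+dy, c+dx).

    Accepts (H, W) images, channel-first (C, H, W) stacks with C <= 4, or
    channel-last (H, W, C) images.
    """
    image = np.asarray(image)
    order = _ORDER[interpolation]
    mode = _MODE[fill]

    def _warp2d(img2d):
        if img2d.shape != f.shape:
            raise ValueError("field and image dimensions differ")
        rr, cc = np.mgrid[0 : img2d.shape[0], 0 : img2d.shape[1]].astype(float)
        coords = np.stack([rr + f.dy, cc + f.dx])
        return map_coordinates(
            img2d.astype(float), coords, order=order, mode=mode, cval=cval
        )

    if image.ndim == 2:
        return _warp2d(image).astype(image.dtype, copy=False)
    if image.ndim == 3:
        if image.shape[0] <= 4 and image.shape[0] < image.shape[-1]:
            out = np.stack([_warp2d(image[c]) for c in range(image.shape[0])])
        else:
            out = np.stack(
                [_warp2d(image[..., c]) for c in range(image.shape[-1])], axis=-1
            )
        return out.astype(image.dtype, copy=False)
    raise ValueError("expected a 2-D image or a 3-D channel stack")


def invert_field(f: DeformationField, iterations: int = 20) -> DeformationField:
    """Numeric fixed-point inversion of a displacement field."""
    inv_dy = np.zeros_like(f.dy)
    inv_dx = np.zeros_like(f.dx)
    rr, cc = np.mgrid[0 : f.shape[0], 0 : f.shape[1]].astype(float)
    for _ in range(iterations):
        sample_y = map_coordinates(f.dy, [rr + inv_dy, cc + inv_dx], order=1, mode="nearest")
        sample_x = map_coordinates(f.dx, [rr + inv_dy, cc + inv_dx], order=1, mode="nearest")
        inv_dy, inv_dx = -sample_y, -sample_x
    return DeformationField(dy=inv_dy, dx=inv_dx)
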