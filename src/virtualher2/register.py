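"""Cross-modality registration of autofluorescence and brightfield WSIs.

The training-data preparation workflow:

1. global feature-based alignment — blob-style keypoints (ORB) detected on
   a representative channel of each modality (AF DAPI channel vs. inverted
   brightfield luminance), binary descriptor matching, robust similarity
   estimation with RANSAC;
2. tiling of the coarsely aligned WSIs into co-located tile pairs
   (1024 x 1024 by default);
3. style-bridge-assisted pyramid elastic registration — a bridge model
   translates AF tiles into brightfield style so that correlation-based
   block matching across modalities is well posed; block shifts estimated
   per pyramid level (coarse to fine) are interpolated to a dense
   displacement field, smoothed, and composed;
4. an iterated train-register loop: refresh the bridge on the current
   pairs, re-register the targets, and repeat (up to 5 rounds) until the
   median residual displacement falls below tolerance; a cleaning pass
   flags pairs with poor correlation or little tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter, map_coordinates, zoom
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .synth import warp_image
from .types import AffineTransform, DeformationField, RegistrationError, TilePair


def af_representative(af: np.ndarray) -> np.ndarray:
    """Representative grayscale channel of a (4, H, W) AF stack (DAPI)."""
    return np.asarray(af)[0]


def brightfield_representative(rgb: np.ndarray) -> np.ndarray:
    """Inverted luminance of an (H, W, 3) brightfield image (stain = bright)."""
    rgb = np.asarray(rgb)
    lum = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
    return 1.0 - lum


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] == 3:
        return brightfield_representative(img)
    if img.ndim == 3 and img.shape[0] <= 4:
        return af_representative(img)
    raise ValueError("cannot reduce image to a representative channel")


def global_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    n_keypoints: int = 800,
    residual_threshold: float = 2.0,
    min_inliers: int = 3,
    max_trials: int = 1000,
    seed: int = 0,
) -> AffineTransform:
    """Robust global similarity transform mapping `moving` onto `fixed`.

    Keypoints + binary descriptors are matched across modalities and a
    similarity transform is estimated with RANSAC; the RMS residual over
    inliers is reported.  Raises :class:`RegistrationError` when fewer than
    `min_inliers` consistent matches exist (unusable slide).
    """
    mg, fg = _as_gray(moving), _as_gray(fixed)
    try:
        orb_m = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        orb_m.detect_and_extract(mg)
        orb_f = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        orb_f.detect_and_extract(fg)
    except (RuntimeError, ValueError) as exc:
        raise RegistrationError(f"feature detection failed: {exc}") from exc
    if len(orb_m.keypoints) < min_inliers or len(orb_f.keypoints) < min_inliers:
        raise RegistrationError("too few detectable features")
    matches = match_descriptors(
        orb_m.descriptors, orb_f.descriptors, cross_check=True
    )
    if len(matches) < min_inliers:
        raise RegistrationError("too few descriptor matches")
    src = orb_m.keypoints[matches[:, 0]]  # (row, col)
    dst = orb_f.keypoints[matches[:, 1]]
    model, inliers = ransac(
        (src, dst),
        SimilarityTransform,
        min_samples=2,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < min_inliers:
        raise RegistrationError("RANSAC found no consistent transform")
    pred = model(src[inliers])
    residual = float(np.sqrt(np.mean(np.sum((pred - dst[inliers]) ** 2, axis=1))))
    matrix = model.params[:2, :]  # rows act on (row, col, 1) as supplied
    return AffineTransform(
        matrix=matrix, inlier_count=int(inliers.sum()), residual=residual
    )


def resample_affine(
    image: np.ndarray, transform: AffineTransform, output_shape: tuple | None = None
) -> np.ndarray:
    """Warp `moving` into the fixed frame using the estimated transform."""
    img2 = _as_gray(image) if image.ndim == 2 else image
    H, W = (output_shape or (np.asarray(image).shape[-2:] if image.ndim == 3 and image.shape[0] <= 4 else np.asarray(image).shape[:2]))
    A = np.vstack([transform.matrix, [0.0, 0.0, 1.0]])
    Ainv = np.linalg.inv(A)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    dy = Ainv[0, 0] * rr + Ainv[0, 1] * cc + Ainv[0, 2] - rr
    dx = Ainv[1, 0] * rr + Ainv[1, 1] * cc + Ainv[1, 2] - cc
    return warp_image(image, DeformationField(dy=dy, dx=dx))


def crop_tile_pairs(
    moving_aligned: np.ndarray,
    fixed: np.ndarray,
    tile_size: int = 1024,
    stride: int | None = None,
) -> list[TilePair]:
    """Cut two globally aligned WSIs into co-located tile pairs.

    `moving_aligned` is the (4, H, W) AF stack, `fixed` the (H, W, 3)
    brightfield WSI.  Tiles are laid on a regular grid; partial border
    tiles are dropped.
    """
    stride = stride or tile_size
    af = np.asarray(moving_aligned)
    bf = np.asarray(fixed)
    H, W = af.shape[-2:]
    if bf.shape[:2] != (H, W):
        raise ValueError("WSI dimensions differ")
    if tile_size > H or tile_size > W:
        raise ValueError("tile_size exceeds WSI dimensions")
    pairs = []
    for r in range(0, H - tile_size + 1, stride):
        for c in range(0, W - tile_size + 1, stride):
            pairs.append(
                TilePair(
                    af=af[:, r : r + tile_size, c : c + tile_size],
                    target=bf[r : r + tile_size, c : c + tile_size],
                    origin=(r, c),
                )
            )
    return pairs


def _block_grid(n: int, bs: int, step: int) -> np.ndarray:
    starts = np.arange(0, max(n - bs, 0) + 1, step)
    if starts[-1] != n - bs:
        starts = np.append(starts, n - bs)
    return np.unique(starts)


def _block_shift_ncc(a: np.ndarray, b: np.ndarray, search: int, peak_min: float = 0.2):
    """Shift (dy, dx) maximizing NCC such that b(r - s) matches a(r).

    The interior of `b` is slid over `a` within +/- `search` pixels; the NCC
    peak is refined to subpixel precision by a 1-D parabola fit per axis.
    Returns None when the template is flat or the peak correlation is weak.
    """
    from skimage.feature import match_template

    bs = a.shape[0]
    if bs - 2 * search < 8:
        search = max((bs - 8) // 2, 1)
    sub = b[search:-search, search:-search]
    if sub.std() < 1e-6 or a.std() < 1e-6:
        return None
    cc = match_template(a, sub)  # (2*search+1, 2*search+1)
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    if cc[iy, ix] < peak_min:
        return None

    def _subpix(v, i):
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            if denom < 0:
                return i + 0.5 * (v[i - 1] - v[i + 1]) / denom
        return float(i)

    py = _subpix(cc[:, ix], iy)
    px = _subpix(cc[iy, :], ix)
    # template found at offset (py, px); centered position is `search`
    sy, sx = py - search, px - search
    # sub placed at +s in a  =>  a(r) ~ b(r - s)
    return np.array([sy, sx])


def pyramid_elastic_register(
    style_matched: np.ndarray,
    target: np.ndarray,
    levels: int = 3,
    block_size: int = 192,
    overlap: float = 0.5,
    smooth_factor: float = 6.0,
    search: int = 10,
) -> DeformationField:
    """Coarse-to-fine block-matching elastic registration.

    Returns the pull-back field warping `target` onto the geometry of
    `style_matched`.  At each pyramid level (x4, x2, x1 downsampling for 3
    levels) overlapping blocks are matched by subpixel cross-correlation;
    block displacements (flat blocks imputed from their neighbors) are
    interpolated to a dense field, Gaussian-smoothed with sigma =
    block/`smooth_factor`, and composed with the running field.
    """
    ref = _as_gray(style_matched)
    tgt = _as_gray(target)
    if ref.shape != tgt.shape:
        raise ValueError("images must share dimensions")
    H, W = ref.shape
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    # constant block size in level coordinates: the physical matching extent
    # is `block_size` at the coarsest level and shrinks as resolution grows
    bs_level = max(block_size // factors[0], 16)
    if bs_level > min(H, W) // factors[0]:
        raise ValueError("block_size larger than the image at the coarsest level")
    total = DeformationField(dy=np.zeros((H, W)), dx=np.zeros((H, W)))

    for factor in factors:
        warped = warp_image(tgt, total)
        if factor > 1:
            ref_s = zoom(ref, 1.0 / factor, order=1)
            tgt_s = zoom(warped, 1.0 / factor, order=1)
        else:
            ref_s, tgt_s = ref, warped
        h, w = ref_s.shape
        bs = min(bs_level, h, w)
        step = max(int(bs * (1.0 - overlap)), 1)
        rows = _block_grid(h, bs, step)
        cols = _block_grid(w, bs, step)
        disp = np.full((len(rows), len(cols), 2), np.nan)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                a = ref_s[r : r + bs, c : c + bs]
                b = tgt_s[r : r + bs, c : c + bs]
                shift = _block_shift_ncc(a, b, search)
                if shift is None:
                    continue  # flat or unreliable block: impute later
                # b shifted by `shift` registers onto a => pull-back d = -shift
                disp[i, j] = -shift
        if np.isnan(disp[..., 0]).all():
            continue  # nothing measurable at this level
        for k in range(2):
            disp[..., k] = _fill_nan_nearest(disp[..., k])
        centers_r = rows + (bs - 1) / 2.0
        centers_c = cols + (bs - 1) / 2.0
        dense = _interp_block_field(disp, centers_r, centers_c, (h, w))
        sigma = bs / smooth_factor
        dy = gaussian_filter(dense[..., 0], sigma) * factor
        dx = gaussian_filter(dense[..., 1], sigma) * factor
        if factor > 1:
            dy = zoom(dy, (H / dy.shape[0], W / dy.shape[1]), order=1)
            dx = zoom(dx, (H / dx.shape[0], W / dx.shape[1]), order=1)
        total = compose_fields(DeformationField(dy=dy, dx=dx), total)
    return total


def _fill_nan_nearest(grid: np.ndarray) -> np.ndarray:
    """Impute NaN block displacements from the nearest valid block."""
    if not np.isnan(grid).any():
        return grid
    from scipy.ndimage import distance_transform_edt

    mask = np.isnan(grid)
    if mask.all():
        return np.zeros_like(grid)
    _, idx = distance_transform_edt(mask, return_indices=True)
    return grid[tuple(idx)]


def _interp_block_field(
    disp: np.ndarray, centers_r: np.ndarray, centers_c: np.ndarray, shape: tuple
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    out = np.empty(shape + (2,))
    for k in range(2):
        if len(centers_r) == 1 and len(centers_c) == 1:
            out[..., k] = disp[0, 0, k]
            continue
        interp = RegularGridInterpolator(
            (centers_r, centers_c), disp[..., k],
            bounds_error=False, fill_value=None, method="linear",
        )
        out[..., k] = interp(pts).reshape(shape)
    return out


def compose_fields(f_outer: DeformationField, f_inner: DeformationField) -> DeformationField:
    """Pull-back composition: (f_outer o f_inner)(r) = f_outer(r) + f_inner(r + f_outer(r))."""
    H, W = f_outer.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    sy = map_coordinates(f_inner.dy, [rr + f_outer.dy, cc + f_outer.dx], order=1, mode="nearest")
    sx = map_coordinates(f_inner.dx, [rr + f_outer.dy, cc + f_outer.dx], order=1, mode="nearest")
    return DeformationField(dy=f_outer.dy + sy, dx=f_outer.dx + sx)


def recover_warp(
    reference: np.ndarray,
    warped: np.ndarray,
    elastic_passes: int = 5,
    tol: float = 0.1,
    **elastic_kwargs,
) -> DeformationField:
    """Recover the full pull-back field aligning `warped` onto `reference`.

    Global feature-based similarity registration provides the affine part;
    iterated pyramid elastic passes (composed, early-stopped once the
    median per-pass correction falls below `tol` pixels) refine the local
    deformation.  ``warp_image(warped, field)`` then reproduces
    `reference`.
    """
    t = global_register(warped, reference)
    A = np.vstack([t.matrix, [0.0, 0.0, 1.0]])
    Ainv = np.linalg.inv(A)
    ref_g = _as_gray(reference)
    H, W = ref_g.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    dy = Ainv[0, 0] * rr + Ainv[0, 1] * cc + Ainv[0, 2] - rr
    dx = Ainv[1, 0] * rr + Ainv[1, 1] * cc + Ainv[1, 2] - cc
    total = DeformationField(dy=dy, dx=dx)
    for _ in range(elastic_passes):
        current = warp_image(warped, total)
        f = pyramid_elastic_register(reference, current, **elastic_kwargs)
        total = compose_fields(f, total)
        if float(np.median(f.magnitude())) < tol:
            break
    return total


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


# --------------------------------------------------------------------------
# style bridges and the iterated refinement loop
# --------------------------------------------------------------------------


class LinearStyleBridge:
    """Pixel-wise linear AF -> brightfield-style translator.

    Regresses the per-pixel optical density of the target image on the four
    AF channels (plus intercept) over all pairs, then renders predictions
    through Beer-Lambert transmission.  Serves as a fast style bridge for
    correlation-based registration; its fit sharpens as registration
    improves across refinement rounds.
    """

    def __init__(self, subsample: int = 4, eps: float = 1e-6):
        self.subsample = subsample
        self.eps = eps
        self.coef_: np.ndarray | None = None

    def fit(self, pairs: list[TilePair]) -> "LinearStyleBridge":
        xs, ys = [], []
        for p in pairs:
            af = np.asarray(p.af, dtype=float)
            tgt = np.asarray(p.target, dtype=float)
            s = self.subsample
            a = af[:, ::s, ::s].reshape(af.shape[0], -1).T
            od = -np.log10(np.maximum(tgt[::s, ::s], self.eps)).reshape(-1, 3)
            xs.append(a)
            ys.append(od)
        X = np.concatenate(xs)
        X = np.column_stack([X, np.ones(len(X))])
        Y = np.concatenate(ys)
        self.coef_, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return self

    def __call__(self, af: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("bridge is not fitted")
        af = np.asarray(af, dtype=float)
        C, H, W = af.shape
        X = np.column_stack([af.reshape(C, -1).T, np.ones(H * W)])
        od = (X @ self.coef_).reshape(H, W, 3)
        return np.clip(np.power(10.0, -np.clip(od, 0.0, None)), 0.0, 1.0)


class NetworkStyleBridge:
    """Style bridge backed by the virtual-staining generator architecture.

    Fine-tunes a (reduced) generator on the current pairs for a fixed
    number of steps each round, keeping parameters across rounds.
    """

    def __init__(self, gen_cfg=None, steps_per_round: int = 100, crop: int = 64,
                 batch: int = 4, lr: float = 1e-3, seed: int = 0):
        from .network import GeneratorConfig, build_generator
        from .nn import AdamW

        cfg = gen_cfg or GeneratorConfig().reduced(8)
        self.model = build_generator(cfg, seed=seed)
        self.opt = AdamW(self.model.parameters(), lr=lr)
        self.steps_per_round = steps_per_round
        self.crop, self.batch = crop, batch
        self.rng = np.random.default_rng(seed)

    def fit(self, pairs: list[TilePair]) -> "NetworkStyleBridge":
        from .network import smooth_l1
        from .nn import Tensor

        for _ in range(self.steps_per_round):
            xb, yb = [], []
            for _ in range(self.batch):
                p = pairs[self.rng.integers(len(pairs))]
                h, w = p.af.shape[-2:]
                r = int(self.rng.integers(0, h - self.crop + 1))
                c = int(self.rng.integers(0, w - self.crop + 1))
                xb.append(p.af[:, r : r + self.crop, c : c + self.crop].transpose(1, 2, 0))
                yb.append(p.target[r : r + self.crop, c : c + self.crop])
            out = self.model(np.stack(xb).astype(np.float32))
            loss = smooth_l1(out, Tensor(np.stack(yb).astype(np.float32)))
            self.opt.zero_grad()
            loss.backward()
            self.opt.step()
        return self

    def __call__(self, af: np.ndarray) -> np.ndarray:
        out = self.model.infer(np.asarray(af, dtype=np.float32))
        return np.clip(out.transpose(1, 2, 0), 0.0, 1.0)


@dataclass
class RefineResult:
    """Outcome of the iterated train-register refinement loop."""

    pairs: list
    residuals: list = field(default_factory=list)  # median per round, px
    rounds: int = 0
    converged: bool = False
    diverged: bool = False


def iterate_refine(
    pairs: list[TilePair],
    trainer=None,
    max_rounds: int = 5,
    tol: float = 0.5,
    ncc_min: float = 0.5,
    tissue_min: float = 0.10,
    register_kwargs: dict | None = None,
) -> RefineResult:
    """Iterated style-bridge training + elastic registration of tile pairs.

    Each round refreshes the bridge on the current pairs, elastic-registers
    every target to its bridge output, applies the fields, and records the
    median residual displacement.  Stops early below `tol`, halts (flagged)
    if the residual grows on two consecutive rounds, and finally flags
    pairs with post-registration NCC < `ncc_min` or tissue fraction below
    `tissue_min` as not clean.
    """
    if not 1 <= max_rounds <= 5:
        raise ValueError("max_rounds must lie in 1..5")
    trainer = trainer or (lambda prs: LinearStyleBridge().fit(prs))
    register_kwargs = register_kwargs or {}
    result = RefineResult(pairs=pairs)

    for _ in range(max_rounds):
        bridge = trainer(pairs)
        round_residuals = []
        for p in pairs:
            style = bridge(p.af)
            f = pyramid_elastic_register(style, p.target, **register_kwargs)
            p.target = warp_image(p.target, f)
            p.registration_residual = float(np.median(f.magnitude()))
            round_residuals.append(p.registration_residual)
        result.rounds += 1
        result.residuals.append(float(np.median(round_residuals)))
        if result.residuals[-1] < tol:
            result.converged = True
            break
        if (
            len(result.residuals) >= 3
            and result.residuals[-1] > result.residuals[-2] > result.residuals[-3]
        ):
            result.diverged = True
            break

    bridge = trainer(pairs)
    for p in pairs:
        style = bridge(p.af)
        tissue = float((brightfield_representative(p.target) > 0.05).mean())
        corr = normalized_cross_correlation(
            brightfield_representative(style),
            brightfield_representative(p.target),
        )
        p.clean = corr >= ncc_min and tissue >= tissue_min
    return result
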