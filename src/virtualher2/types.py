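"""Shared domain types for the virtual HER2 staining pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class HER2Score(IntEnum):
    """Semi-quantitative HER2 IHC score (HercepTest convention).

    Ordinal levels 0 < 1+ < 2+ < 3+; 0/1+ are negative, 2+ equivocal,
    3+ positive.
    """

    ZERO = 0
    ONE = 1
    TWO = 2
    THREE = 3

    @property
    def label(self) -> str:
        return "0" if self == 0 else f"{int(self)}+"

    @classmethod
    def from_label(cls, label) -> "HER2Score":
        if isinstance(label, HER2Score):
            return label
        if isinstance(label, (int, np.integer)):
            return cls(int(label))
        s = str(label).strip().rstrip("+")
        try:
            return cls(int(s))
        except ValueError as exc:
            raise ValueError(f"unknown HER2 score label: {label!r}") from exc


SCORE_LABELS = tuple(s.label for s in HER2Score)


@dataclass
class LatentTissueMap:
    """Ground-truth tissue geometry underlying one synthetic tile.

    ``membrane_density`` and ``nucleus_density`` carry the per-pixel DAB and
    hematoxylin optical densities implied by the grade model, so rendering
    is a deterministic function of the latent map.
    """

    nucleus_mask: np.ndarray
    nucleus_labels: np.ndarray
    nucleus_density: np.ndarray
    membrane_mask: np.ndarray
    membrane_density: np.ndarray
    complete_ring_flags: np.ndarray
    stroma_field: np.ndarray
    height: int
    width: int

    @property
    def n_cells(self) -> int:
        return int(self.nucleus_labels.max())

    def complete_ring_fraction(self) -> float:
        n = self.n_cells
        return float(self.complete_ring_flags.sum()) / n if n else 0.0


@dataclass
class SyntheticPair:
    """A registered synthetic training pair: AF stack + brightfield IHC."""

    af: np.ndarray  # (4, H, W) float32 in [0, 1]
    ihc: np.ndarray  # (H, W, 3) float32 in [0, 1]
    latent: LatentTissueMap
    grade: HER2Score
    seed: int


@dataclass(frozen=True)
class WarpSpec:
    """Parametric ground-truth warp: affine + smooth sinusoidal elastic part."""

    affine: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    )
    elastic_amplitude: float = 0.0
    elastic_period: float = 128.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (2, 3):
            raise ValueError("affine must be a 2x3 matrix")
        if self.elastic_amplitude < 0:
            raise ValueError("elastic_amplitude must be >= 0")
        if self.elastic_period <= 0:
            raise ValueError("elastic_period must be positive")


@dataclass
class DeformationField:
    """Dense pull-back displacement: output(r, c) = source(r + dy, c + dx)."""

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self):
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must have the same shape")

    @property
    def shape(self):
        return self.dy.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    def smoothness(self) -> float:
        """Maximum local displacement gradient (per-axis finite differences)."""
        grads = []
        for comp in (self.dy, self.dx):
            gy, gx = np.gradient(comp)
            grads.append(np.abs(gy).max())
            grads.append(np.abs(gx).max())
        return float(max(grads))


@dataclass
class AffineTransform:
    """Global similarity/affine registration result in (row, col) pixels."""

    matrix: np.ndarray  # 2x3; [r', c'] = matrix @ [r, c, 1]
    inlier_count: int
    residual: float  # RMS over inliers, pixels

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass
class TilePair:
    """One co-located AF / brightfield tile pair cropped from aligned WSIs."""

    af: np.ndarray  # (4, h, w)
    target: np.ndarray  # (h, w, 3)
    origin: tuple  # (row, col) in the WSI frame
    registration_residual: float = float("nan")
    clean: bool = True
    patient_id: str = "unknown"
    tile_id: str = ""


class RegistrationError(RuntimeError):
    """Global feature-based registration could not find a usable transform."""


class DegenerateThresholdError(ValueError):
    """Otsu thresholding is undefined (constant stain channel)."""
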