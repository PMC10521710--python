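"""Blinded-study arithmetic: ROI sampling, confusion matrices and tests.

Reproduces the reader-study computations used to compare virtual and
chemically stained HER2 slides: 4x4 confusion matrices of assigned vs.
reference HER2 scores (rows = pathologist assignment, columns =
reference), their diagonal sums and weighted off-diagonal errors
(sum of count x |assigned - reference| over off-diagonal cells), a
two-sided Pearson chi-square comparison of the two modalities, and
one-sided paired t-tests on 1-4 staining-quality grades (virtual minus
IHC differences tested against zero with alternative "IHC better").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import HER2Score

log = logging.getLogger(__name__)

QUALITY_METRICS = (
    "nuclear_detail",
    "membrane_clearness",
    "background",
    "artifacts",
)

SCORE_COLUMNS = ("wsi_id", "patient_id", "modality", "reader_id", "assigned", "reference")
QUALITY_COLUMNS = ("roi_id", "modality", "reader_id", "metric", "grade")


def validate_score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/coerce a long-form HER2 score table."""
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    out = df.copy()
    for col in ("assigned", "reference"):
        out[col] = out[col].map(lambda v: int(HER2Score.from_label(v)))
    bad = set(out["modality"]) - {"virtual", "ihc"}
    if bad:
        raise ValueError(f"unknown modalities: {sorted(bad)}")
    dup = out.duplicated(subset=["wsi_id", "reader_id", "modality"])
    if dup.any():
        raise ValueError("duplicate (wsi, reader, modality) records")
    return out


def validate_quality_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(QUALITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"quality table missing columns: {sorted(missing)}")
    out = df.copy()
    ok = out["grade"].isna() | out["grade"].isin([1, 2, 3, 4])
    if not ok.all():
        raise ValueError("grades must be 1-4 (or missing for N/A)")
    if not set(out["metric"]).issubset(QUALITY_METRICS):
        raise ValueError("unknown quality metric")
    return out


# --------------------------------------------------------------------------
# ROI sampling harness
# --------------------------------------------------------------------------


@dataclass
class ROIPair:
    wsi_id: str
    roi_id: str
    origin: tuple
    virtual: np.ndarray
    ihc: np.ndarray


def sample_rois(
    wsis,
    n_per_wsi: int = 10,
    roi_size: int = 8000,
    seed: int = 0,
    min_tissue: float = 0.02,
    max_tries: int = 50,
) -> list[ROIPair]:
    """Extract co-located ROIs from paired virtual/IHC WSIs.

    `wsis` is an iterable of (wsi_id, virtual, ihc) with (H, W, 3) images.
    ROIs are drawn at identical coordinates in both modalities, preferring
    positions whose tissue fraction exceeds `min_tissue`.
    """
    from .register import brightfield_representative

    rng = np.random.default_rng(seed)
    rois = []
    for wsi_id, virt, ihc in wsis:
        virt = np.asarray(virt)
        ihc = np.asarray(ihc)
        if virt.shape != ihc.shape:
            raise ValueError(f"{wsi_id}: modality shapes differ")
        H, W = virt.shape[:2]
        if roi_size > H or roi_size > W:
            raise ValueError(f"{wsi_id}: WSI smaller than roi_size")
        for k in range(n_per_wsi):
            origin = None
            for _ in range(max_tries):
                r = int(rng.integers(0, H - roi_size + 1))
                c = int(rng.integers(0, W - roi_size + 1))
                patch = ihc[r : r + roi_size, c : c + roi_size]
                if (brightfield_representative(patch) > 0.05).mean() >= min_tissue:
                    origin = (r, c)
                    break
            if origin is None:
                origin = (r, c)  # fall back to the last draw
            r, c = origin
            rois.append(
                ROIPair(
                    wsi_id=wsi_id,
                    roi_id=f"{wsi_id}/roi{k:02d}",
                    origin=origin,
                    virtual=virt[r : r + roi_size, c : c + roi_size],
                    ihc=ihc[r : r + roi_size, c : c + roi_size],
                )
            )
    return rois


# --------------------------------------------------------------------------
# confusion matrices
# --------------------------------------------------------------------------


def build_confusion(records: pd.DataFrame, modality: str) -> np.ndarray:
    """4x4 confusion matrix (rows assigned, columns reference) for a modality."""
    df = validate_score_table(records)
    sel = df[df["modality"] == modality]
    if sel.empty:
        raise ValueError(f"no records for modality {modality!r}")
    m = np.zeros((4, 4), dtype=int)
    for a, r in zip(sel["assigned"], sel["reference"]):
        m[a, r] += 1
    return m


def confusion_summaries(m: np.ndarray) -> tuple[int, int]:
    """(diagonal sum, weighted off-diagonal error sum count x |i - j|)."""
    m = np.asarray(m)
    if m.shape != (4, 4) or (m < 0).any():
        raise ValueError("expected a non-negative 4x4 matrix")
    diag = int(np.trace(m))
    idx = np.arange(4)
    weights = np.abs(idx[:, None] - idx[None, :])
    weighted = int((m * weights).sum())
    return diag, weighted


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int
    table: np.ndarray
    expected: np.ndarray
    small_expected: bool


def chi_square_agreement(
    virtual_m: np.ndarray | None = None,
    ihc_m: np.ndarray | None = None,
    layout: str = "assigned_by_modality",
    table: np.ndarray | None = None,
) -> ChiSquareResult:
    """Two-sided Pearson chi-square comparing the two scoring modalities.

    The contingency construction is a pluggable policy:

    * ``assigned_by_modality`` — 2 x 4 table of assigned-score counts per
      modality (row margins of the confusion matrices);
    * ``concordance`` — 2 x 2 table of concordant vs. discordant counts;
    * an explicit `table` bypasses the layout entirely.

    Zero-margin categories are collapsed (logged); a flag reports expected
    counts below 5.
    """
    if table is None:
        if virtual_m is None or ihc_m is None:
            raise ValueError("need both confusion matrices (or an explicit table)")
        virtual_m = np.asarray(virtual_m)
        ihc_m = np.asarray(ihc_m)
        if virtual_m.sum() != ihc_m.sum():
            raise ValueError("matrices must aggregate the same number of records")
        if layout == "assigned_by_modality":
            table = np.stack([virtual_m.sum(axis=1), ihc_m.sum(axis=1)])
        elif layout == "concordance":
            dv, _ = confusion_summaries(virtual_m)
            di, _ = confusion_summaries(ihc_m)
            n = int(virtual_m.sum())
            table = np.array([[dv, n - dv], [di, n - di]])
        else:
            raise ValueError(f"unknown layout {layout!r}")
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    if not keep.all():
        log.warning("collapsing %d zero-margin categories", (~keep).sum())
        table = table[:, keep]
    if table.shape[1] < 2:
        # no variation across categories: identical distributions
        return ChiSquareResult(0.0, 1.0, 0, table, table.copy(), False)
    res = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(res.dof),
        table=table,
        expected=np.asarray(res.expected_freq),
        small_expected=bool((np.asarray(res.expected_freq) < 5).any()),
    )


# --------------------------------------------------------------------------
# paired quality t-tests
# --------------------------------------------------------------------------


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    n: int
    direction: str  # alternative hypothesis: mean(virtual - ihc) < 0
    mean_difference: float


def paired_quality_ttest(
    records: pd.DataFrame, metric: str, reader_id
) -> TTestResult:
    """One-sided paired t-test of quality grades (is IHC better than virtual?).

    Differences d = virtual - IHC are formed per ROI; the alternative is
    mean(d) < 0 (standard IHC scores higher).  ROIs with a missing grade in
    either modality (e.g. membrane clearness on HER2-negative tissue) are
    dropped.  All-zero differences return the p = 0.5 convention; constant
    nonzero differences return the degenerate limit p in {0, 1} with an
    infinite statistic.
    """
    df = validate_quality_table(records)
    sel = df[(df["metric"] == metric) & (df["reader_id"] == reader_id)]
    wide = sel.pivot_table(
        index="roi_id", columns="modality", values="grade", aggfunc="first",
        dropna=False,
    )
    if "virtual" not in wide.columns or "ihc" not in wide.columns:
        raise ValueError("need both modalities for a paired test")
    wide = wide.dropna()
    d = (wide["virtual"] - wide["ihc"]).to_numpy(dtype=float)
    if len(d) < 2:
        raise ValueError("fewer than 2 complete pairs")
    mean_d = float(d.mean())
    if d.std(ddof=1) == 0:
        if mean_d == 0:
            return TTestResult(0.0, 0.5, len(d), "less", 0.0)
        stat = -np.inf if mean_d < 0 else np.inf
        return TTestResult(float(stat), 0.0 if mean_d < 0 else 1.0, len(d), "less", mean_d)
    res = sps.ttest_1samp(d, 0.0, alternative="less")
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(d),
        direction="less",
        mean_difference=mean_d,
    )
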