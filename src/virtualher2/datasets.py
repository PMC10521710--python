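"""Synthetic reader-study tables for exercising the stats module.

The real blinded-study score sheets are private clinical data, so this
module constructs synthetic stand-ins with the same structure and a
realistic error profile: 12 WSIs (three per HER2 grade), three readers,
both modalities scored per WSI, and errors that are predominantly
single-step on the ordinal scale.  The virtual-modality table carries 22
concordant evaluations with a weighted off-diagonal error of 14; the IHC
table carries 19 concordant evaluations with a weighted error of 18 —
the summary profile of the blinded study this harness emulates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import QUALITY_METRICS
from .types import HER2Score

#: Reference (ground-truth) HER2 grade per synthetic WSI.
REFERENCE_GRADES = {
    f"w{i + 1:02d}": g for i, g in enumerate([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3])
}

# Reader assignments that deviate from the reference, per modality.
# virtual: 14 discordant reads, all one step off (diagonal sum 22).
_VIRTUAL_ERRORS = {
    "R1": {"w03": 1, "w04": 0, "w07": 1, "w10": 2},
    "R2": {"w05": 2, "w06": 0, "w08": 3, "w09": 1, "w11": 2},
    "R3": {"w01": 1, "w02": 1, "w06": 2, "w09": 3, "w12": 2},
}
# ihc: 17 discordant reads, sixteen one step and one two steps off
# (diagonal sum 19, weighted error 18).
_IHC_ERRORS = {
    "R1": {"w02": 1, "w03": 1, "w05": 0, "w08": 1, "w11": 2},
    "R2": {"w01": 1, "w04": 2, "w07": 3, "w10": 1, "w12": 2},
    "R3": {"w02": 1, "w03": 1, "w05": 2, "w06": 2, "w09": 3, "w10": 2, "w12": 2},
}


def synthetic_reader_study() -> pd.DataFrame:
    """Long-form synthetic HER2 score table (12 WSIs x 3 readers x 2 modalities)."""
    rows = []
    for modality, errors in (("virtual", _VIRTUAL_ERRORS), ("ihc", _IHC_ERRORS)):
        for reader in ("R1", "R2", "R3"):
            for wsi, ref in REFERENCE_GRADES.items():
                assigned = errors.get(reader, {}).get(wsi, ref)
                rows.append(
                    {
                        "wsi_id": wsi,
                        "patient_id": f"P{wsi[1:]}",
                        "modality": modality,
                        "reader_id": reader,
                        "assigned": HER2Score(assigned).label,
                        "reference": HER2Score(ref).label,
                    }
                )
    return pd.DataFrame(rows)


def synthetic_quality_scores(seed: int = 0, n_rois_per_wsi: int = 10) -> pd.DataFrame:
    """Synthetic 1-4 staining-quality grades for paired virtual/IHC ROIs.

    Emulates the blinded quality review: both modalities score high on all
    four metrics, standard IHC holds a slight edge on freedom from
    background staining, and membrane clearness is not applicable
    (missing) on HER2-negative ROIs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for wsi, ref in REFERENCE_GRADES.items():
        for k in range(n_rois_per_wsi):
            roi = f"{wsi}/roi{k:02d}"
            for reader in ("R1", "R2", "R3"):
                for metric in QUALITY_METRICS:
                    for modality in ("virtual", "ihc"):
                        if metric == "membrane_clearness" and ref <= 1:
                            grade = np.nan
                        else:
                            base = 3.4 if metric != "background" else 3.2
                            if metric == "background" and modality == "ihc":
                                base += 0.45
                            grade = float(
                                np.clip(round(base + rng.normal(0, 0.55)), 1, 4)
                            )
                        rows.append(
                            {
                                "roi_id": roi,
                                "modality": modality,
                                "reader_id": reader,
                                "metric": metric,
                                "grade": grade,
                            }
                        )
    return pd.DataFrame(rows)
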