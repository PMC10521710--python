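"""Reader-study statistics: confusion matrices, chi-square, paired t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from virtualher2 import stats
from virtualher2.datasets import synthetic_quality_scores, synthetic_reader_study


@pytest.fixture(scope="module")
def score_table():
    return synthetic_reader_study()


def test_confusion_totals_and_concordant_case(score_table):
    m = stats.build_confusion(score_table, "virtual")
    assert m.sum() == 36
    concordant = pd.DataFrame(
        {
            "wsi_id": [f"w{i}" for i in range(8)],
            "patient_id": [f"p{i}" for i in range(8)],
            "modality": ["virtual"] * 8,
            "reader_id": ["R1"] * 8,
            "assigned": ["0", "1+", "2+", "3+"] * 2,
            "reference": ["0", "1+", "2+", "3+"] * 2,
        }
    )
    mc = stats.build_confusion(concordant, "virtual")
    diag, weighted = stats.confusion_summaries(mc)
    assert diag == 8 and weighted == 0
    assert np.trace(mc) == mc.sum()


def test_reader_study_summaries(score_table):
    mv = stats.build_confusion(score_table, "virtual")
    mi = stats.build_confusion(score_table, "ihc")
    assert stats.confusion_summaries(mv) == (22, 14)
    assert stats.confusion_summaries(mi) == (19, 18)


def test_weighted_error_single_cell():
    m = np.zeros((4, 4), dtype=int)
    m[0, 2] = 1  # |0 - 2| = 2
    brute = sum(
        m[i, j] * abs(i - j) for i in range(4) for j in range(4) if i != j
    )
    assert stats.confusion_summaries(m) == (0, 2)
    assert brute == 2


def test_weighted_error_zero_iff_diagonal(rng):
    for _ in range(10):
        m = rng.integers(0, 5, size=(4, 4))
        diag, weighted = stats.confusion_summaries(m)
        assert (weighted == 0) == (diag == m.sum())


def test_chi_square_identical_matrices(score_table):
    m = stats.build_confusion(score_table, "virtual")
    r = stats.chi_square_agreement(m, m.copy())
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed_2x2():
    r = stats.chi_square_agreement(table=np.array([[10, 20], [20, 10]]))
    assert r.statistic == pytest.approx(20 / 3, abs=1e-10)
    brute = 0.0
    table = np.array([[10, 20], [20, 10]], dtype=float)
    rowsum = table.sum(1, keepdims=True)
    colsum = table.sum(0, keepdims=True)
    expected = rowsum @ colsum / table.sum()
    brute = ((table - expected) ** 2 / expected).sum()
    assert r.statistic == pytest.approx(brute, abs=1e-10)


def test_chi_square_row_swap_invariance(score_table):
    mv = stats.build_confusion(score_table, "virtual")
    mi = stats.build_confusion(score_table, "ihc")
    r1 = stats.chi_square_agreement(mv, mi)
    r2 = stats.chi_square_agreement(mi, mv)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


def test_chi_square_requires_matching_totals():
    a = np.zeros((4, 4), dtype=int)
    b = np.zeros((4, 4), dtype=int)
    a[0, 0], b[0, 0] = 3, 4
    with pytest.raises(ValueError):
        stats.chi_square_agreement(a, b)


def test_ttest_all_zero_differences():
    df = pd.DataFrame(
        {
            "roi_id": ["r1", "r1", "r2", "r2", "r3", "r3"],
            "modality": ["virtual", "ihc"] * 3,
            "reader_id": ["R1"] * 6,
            "metric": ["artifacts"] * 6,
            "grade": [3, 3, 4, 4, 2, 2],
        }
    )
    r = stats.paired_quality_ttest(df, "artifacts", "R1")
    assert r.statistic == 0.0 and r.p_value == 0.5


def test_ttest_constant_negative_differences():
    rows = []
    for i in range(4):
        rows.append(("r%d" % i, "virtual", "R1", "background", 2))
        rows.append(("r%d" % i, "ihc", "R1", "background", 3))
    df = pd.DataFrame(rows, columns=["roi_id", "modality", "reader_id", "metric", "grade"])
    r = stats.paired_quality_ttest(df, "background", "R1")
    assert r.p_value < 0.05
    assert r.mean_difference == -1.0


def test_ttest_matches_reference_implementation(rng):
    for _ in range(20):
        n = int(rng.integers(5, 30))
        v = rng.integers(1, 5, n).astype(float)
        i = np.clip(v + rng.normal(0, 0.8, n).round(), 1, 4)
        rows = []
        for k in range(n):
            rows.append((f"r{k}", "virtual", "R1", "nuclear_detail", v[k]))
            rows.append((f"r{k}", "ihc", "R1", "nuclear_detail", i[k]))
        df = pd.DataFrame(
            rows, columns=["roi_id", "modality", "reader_id", "metric", "grade"]
        )
        d = v - i
        if d.std(ddof=1) == 0:
            continue
        r = stats.paired_quality_ttest(df, "nuclear_detail", "R1")
        ref = sps.ttest_rel(v, i, alternative="less")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)


@settings(max_examples=20, deadline=None)
@given(
    hst.floats(min_value=-1.0, max_value=1.0),
    hst.floats(min_value=-1.0, max_value=1.0),
)
def test_ttest_p_monotone_in_mean_difference(shift_a, shift_b):
    base = np.array([0.1, -0.4, 0.3, 0.2, -0.2, 0.15, 0.05, -0.1])
    lo, hi = sorted([shift_a, shift_b])
    t_lo = sps.ttest_1samp(base + lo, 0.0, alternative="less")
    t_hi = sps.ttest_1samp(base + hi, 0.0, alternative="less")
    assert t_lo.pvalue <= t_hi.pvalue + 1e-12


def test_membrane_clearness_missing_pairs_dropped():
    q = synthetic_quality_scores(seed=1, n_rois_per_wsi=2)
    r = stats.paired_quality_ttest(q, "membrane_clearness", "R1")
    # only HER2 2+/3+ WSIs contribute (6 of 12), 2 ROIs each
    assert r.n == 12


def test_quality_table_validation():
    bad = pd.DataFrame(
        {"roi_id": ["a"], "modality": ["virtual"], "reader_id": ["R1"],
         "metric": ["nuclear_detail"], "grade": [7]}
    )
    with pytest.raises(ValueError):
        stats.validate_quality_table(bad)


def test_score_table_validation(score_table):
    with pytest.raises(ValueError):
        stats.build_confusion(score_table, "fluorescence")
    dup = pd.concat([score_table.iloc[:1]] * 2 + [score_table])
    with pytest.raises(ValueError):
        stats.validate_score_table(dup)
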