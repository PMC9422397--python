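"""Confusion tables, the study's diagnostic parameters, and the
significance tests (Yates chi-square, Welch t)."""

import math

import numpy as np
import pytest
from scipy import stats

import thyrodca as tdc


# --- confusion table construction -----------------------------------------


def test_build_confusion_on_published_cohort(paper_cohort):
    ct = tdc.build_confusion(paper_cohort, "grayscale")
    assert (ct.tp_suspicious, ct.tp_benign, ct.fp_suspicious_col, ct.fp_benign_col) == (
        31,
        250,
        24,
        20,
    )
    # standard synonyms map to the arithmetically consistent cells
    assert ct.fn == 24 and ct.fp == 20 and ct.tp == 31 and ct.tn == 250
    assert ct.n_malignant == 55 and ct.n_benign == 270


def test_build_confusion_errors():
    with pytest.raises(ValueError):
        tdc.build_confusion([], "grayscale")
    rec = tdc.NoduleRecord("p1", "n1", 1.0, "benign", {"grayscale": "benign"})
    with pytest.raises(ValueError, match="n1"):
        tdc.build_confusion([rec], "doppler")


def test_perfect_classifier_has_empty_error_cells():
    records = [
        tdc.NoduleRecord(
            "p1",
            f"n{i}",
            1.0,
            cls,
            {"m": "suspicious" if cls == "malignant" else "benign"},
        )
        for i, cls in enumerate(["malignant"] * 5 + ["benign"] * 5)
    ]
    ct = tdc.build_confusion(records, "m")
    assert ct.fp_suspicious_col == 0 and ct.fp_benign_col == 0
    d = tdc.standard_metrics(ct)
    assert (d.sensitivity, d.accuracy_paper, d.ppv_std, d.npv_std) == (1.0, 1.0, 1.0, 1.0)


@pytest.mark.parametrize("seed", range(5))
def test_cell_conservation_on_generated_cohorts(seed):
    """The four cells partition any cohort and the row sums recover the
    FNA margins."""
    records = tdc.generate_cohort(tdc.SynthConfig(seed=seed))
    n_mal = sum(r.fna_class == "malignant" for r in records)
    for m in tdc.MODALITIES:
        ct = tdc.build_confusion(records, m)
        assert ct.tp_suspicious + ct.tp_benign + ct.fp_suspicious_col + ct.fp_benign_col == 325
        assert ct.tp_suspicious + ct.fp_suspicious_col == n_mal
        assert ct.tp_benign + ct.fp_benign_col == 325 - n_mal


def test_inconsistent_cells_rejected():
    with pytest.raises(ValueError, match="sum"):
        tdc.ConfusionTable("x", 10, 10, 10, 10, n_total=41)


# --- diagnostic parameters --------------------------------------------------


@pytest.mark.parametrize(
    "modality, sens, acc",
    [("grayscale", 0.564, 0.926), ("doppler", 0.600, 0.919), ("combined", 0.691, 0.959)],
)
def test_published_sensitivity_and_accuracy(modality, sens, acc):
    ct = tdc.TABLE2_FIXTURE[modality]
    assert tdc.round_half_up(tdc.sensitivity(ct), 3) == sens
    assert tdc.round_half_up(tdc.accuracy_paper(ct), 3) == acc


def test_standard_metric_synonyms():
    d = tdc.standard_metrics(tdc.TABLE2_FIXTURE["grayscale"])
    assert d.ppv_std == pytest.approx(31 / 51)
    assert d.specificity_std == d.accuracy_paper  # the study's "accuracy" is specificity
    d2 = tdc.standard_metrics(tdc.TABLE2_FIXTURE["doppler"])
    assert d2.npv_std == pytest.approx(248 / 270)


def test_zero_denominator_is_nan_flagged():
    ct = tdc.ConfusionTable("m", 0, 10, 0, 2, n_total=12)  # no FNA-malignant nodules
    assert math.isnan(tdc.sensitivity(ct))
    d = tdc.standard_metrics(ct)
    assert math.isnan(d.sensitivity) and not math.isnan(d.accuracy_paper)


# --- Yates chi-square -------------------------------------------------------


def _textbook_yates(a, b, c, d):
    """Continuity-corrected 2x2 chi-square, n(|ad-bc|-n/2)^2 / product of
    margins, with the correction clipped at zero."""
    n = a + b + c + d
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    return n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))


def test_yates_matches_textbook_formula_on_random_tables():
    rng = np.random.default_rng(1234)
    checked = 0
    while checked < 1000:
        n = int(rng.integers(20, 500))
        cm = int(rng.integers(1, n))
        cr = int(rng.integers(1, n))
        chi2, p = tdc.yates_chi_square_vs_reference(cm, cr, n)
        expected = 0.0 if cm == cr else _textbook_yates(cm, n - cm, cr, n - cr)
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 1) if expected > 0 else 1.0, abs=1e-10)
        checked += 1


@pytest.mark.parametrize(
    "count_modality, count_reference, expected_p",
    [
        (31, 55, 0.008),
        (33, 55, 0.016),
        (38, 55, 0.073),
        (250, 270, 0.062),
        (248, 270, 0.041),
        (259, 270, 0.314),
    ],
)
def test_published_p_values_reproduced(count_modality, count_reference, expected_p):
    """Each published detection-count comparison against the FNA
    reference reproduces at 3 decimals under the continuity-corrected
    construction."""
    _, p = tdc.yates_chi_square_vs_reference(count_modality, count_reference, 325)
    assert tdc.round_half_up(p, 3) == expected_p


def test_identical_proportions_give_null_result():
    assert tdc.yates_chi_square_vs_reference(40, 40, 100) == (0.0, 1.0)


def test_degenerate_table_raises():
    with pytest.raises(ValueError, match="degenerate"):
        tdc.yates_chi_square_vs_reference(0, 0, 100)
    with pytest.raises(ValueError, match="degenerate"):
        tdc.yates_chi_square_vs_reference(100, 100, 100)
    with pytest.raises(ValueError, match="count_modality"):
        tdc.yates_chi_square_vs_reference(101, 50, 100)


# --- Welch t ---------------------------------------------------------------


def test_welch_identical_samples():
    x = [1.0, 2.0, 3.0]
    t, p = tdc.welch_t_test(x, x)
    assert (t, p) == (0.0, 1.0)


def test_welch_undersized_sample_raises():
    with pytest.raises(ValueError, match="2 observations"):
        tdc.welch_t_test([1.0], [1.0, 2.0])


def test_welch_null_p_values_are_uniform():
    """Under the null (same distribution) the two-sided p-values are
    uniform on [0, 1] — Kolmogorov–Smirnov check over replicates."""
    rng = np.random.default_rng(99)
    ps = []
    for _ in range(1000):
        a = rng.normal(1.55, 0.16, size=30)
        b = rng.normal(1.55, 0.16, size=30)
        ps.append(tdc.welch_t_test(a, b)[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_welch_from_published_size_summary():
    """From the published size summaries (1.54 +/- 0.16 vs 1.56 +/- 0.17
    cm, n=325 per arm) the Welch test gives p ~ 0.123 — far from the
    published 0.872, which is not recoverable from those summaries."""
    t, p = tdc.welch_t_from_stats(1.54, 0.16, 325, 1.56, 0.17, 325)
    # independent hand computation of the Welch statistic
    se = math.sqrt(0.16**2 / 325 + 0.17**2 / 325)
    assert t == pytest.approx((1.54 - 1.56) / se, rel=1e-12)
    assert tdc.round_half_up(p, 3) == 0.123
    assert abs(p - 0.872) > 0.5
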