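"""2x2 metrics, Cohen's kappa, and integer table reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bjscreen.evaluation import (ConfusionMatrix, ScreeningTargets,
                                 cohen_kappa, cohort_realizing_matrix,
                                 compute_metrics, confusion_matrix,
                                 evaluation_report,
                                 reconstruct_confusion_matrix,
                                 report_markdown)

counts = st.integers(0, 400)


def brute_kappa(cm):
    """Direct p_o / p_e computation, independent of the implementation."""
    n = cm.n
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    return (p_o - p_e) / (1 - p_e)


def test_metrics_on_lambda_rule_matrix():
    """The reconstructed lambda-side screen table (46, 19, 5, 136)."""
    m = compute_metrics(ConfusionMatrix(46, 19, 5, 136))
    assert m.sensitivity == pytest.approx(90.20, abs=0.01)
    assert m.specificity == pytest.approx(87.74, abs=0.01)
    assert m.ppv == pytest.approx(70.77, abs=0.01)
    assert m.npv == pytest.approx(96.45, abs=0.01)
    assert m.fp_rate_total == pytest.approx(9.22, abs=0.01)
    assert m.fn_rate_total == pytest.approx(2.43, abs=0.01)
    assert m.fnr_of_positives == pytest.approx(9.80, abs=0.01)


def test_npv_of_combined_rule_matrix():
    m = compute_metrics(ConfusionMatrix(186, 229, 12, 289))
    assert m.npv == pytest.approx(96.0, abs=0.05)  # 289/301


def test_perfect_screen_metrics():
    m = compute_metrics(ConfusionMatrix(5, 0, 0, 5))
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (100, 100, 100, 100)


def test_undefined_metrics_reported_absent():
    m = compute_metrics(ConfusionMatrix(0, 3, 0, 7))
    assert m.sensitivity is None
    assert "sensitivity" in m.reasons


@given(tp=counts, fp=counts, fn=counts, tn=counts)
def test_metric_identities(tp, fp, fn, tn):
    if tp + fp + fn + tn == 0:
        return
    m = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
    if m.sensitivity is not None:
        assert m.sensitivity + m.fnr_of_positives == pytest.approx(100.0)
    # prevalence decomposition recovers the false negative share
    if m.sensitivity is not None:
        assert m.prevalence * (100 - m.sensitivity) / 100 == pytest.approx(
            m.fn_rate_total
        )


def test_kappa_known_values():
    assert cohen_kappa(ConfusionMatrix(46, 19, 5, 136)).kappa == \
        pytest.approx(0.714, abs=5e-4)
    assert cohen_kappa(ConfusionMatrix(5, 0, 0, 5)).kappa == pytest.approx(1.0)
    assert cohen_kappa(ConfusionMatrix(25, 25, 25, 25)).kappa == \
        pytest.approx(0.0)


def test_kappa_degenerate_marginals_absent():
    assert cohen_kappa(ConfusionMatrix(10, 0, 0, 0)) is None


@given(tp=counts, fp=counts, fn=counts, tn=counts)
def test_kappa_matches_brute_force(tp, fp, fn, tn):
    cm_counts = (tp + 1, fp, fn, tn + 1)  # keep marginals non-degenerate
    cm = ConfusionMatrix(*cm_counts)
    result = cohen_kappa(cm)
    if result is not None:
        assert result.kappa == pytest.approx(brute_kappa(cm), abs=1e-12)
        # SE may be 0 at perfect agreement, collapsing the CI to a point
        assert result.ci_low <= result.kappa <= result.ci_high


def test_confusion_matrix_alignment_and_missing_truth():
    screen = pd.Series({"a": True, "b": False, "c": True})
    truths = pd.Series({"a": "kappa_bjp", "b": "negative", "c": None})
    cm = confusion_matrix(screen, truths)  # c excluded: no truth
    assert cm.as_tuple() == (1, 0, 0, 1)
    with pytest.raises(ValueError, match="aligned"):
        confusion_matrix(screen, pd.Series({"a": "negative", "z": "negative",
                                            "c": "negative"}))


def test_confusion_matrix_all_positive():
    screen = pd.Series({"a": True, "b": True})
    truths = pd.Series({"a": "kappa_bjp", "b": "lambda_bjp"})
    assert confusion_matrix(screen, truths).as_tuple() == (2, 0, 0, 0)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def test_reconstruction_unique_lambda_rule_table():
    result = reconstruct_confusion_matrix(
        {"sensitivity": 90.20, "specificity": 87.74, "ppv": 70.76,
         "fp_rate_total": 9.22, "fn_rate_total": 2.42},
        n_max=300, decimals=2,
    )
    assert result.unique
    assert result.best.as_tuple() == (46, 19, 5, 136)


def test_reconstruction_fixed_n_validation_rule():
    result = reconstruct_confusion_matrix(
        {"sensitivity": 88.9, "specificity": 65.6, "ppv": 49.7,
         "npv": 93.9, "fnr_of_positives": 11.1},
        n=716, decimals=1,
    )
    assert result.best.as_tuple() == (176, 178, 22, 340)


def test_reconstruction_underdetermined_inputs():
    result = reconstruct_confusion_matrix(
        {"sensitivity": 100.0, "specificity": 100.0}, n=10, decimals=1
    )
    assert not result.unique
    assert len(result.candidates) == 9  # every split tp=k, tn=10-k
    for c in result.candidates:
        assert c.matrix.fp == 0 and c.matrix.fn == 0


def test_reconstruction_closest_miss_when_inconsistent():
    result = reconstruct_confusion_matrix(
        {"sensitivity": 60.0, "specificity": 60.0, "ppv": 99.0,
         "npv": 99.0},
        n=10, decimals=1,
    )
    assert result.candidates == []
    assert result.closest is not None


def test_reconstruction_deterministic_ordering():
    reported = {"sensitivity": 80.0, "specificity": 80.0}
    a = reconstruct_confusion_matrix(reported, n=20, decimals=0)
    b = reconstruct_confusion_matrix(reported, n=20, decimals=0)
    assert [c.matrix.as_tuple() for c in a.candidates] == \
        [c.matrix.as_tuple() for c in b.candidates]


@given(tp=st.integers(1, 40), fp=st.integers(0, 40),
       fn=st.integers(0, 40), tn=st.integers(1, 40))
def test_reconstruction_inverts_compute_metrics(tp, fp, fn, tn):
    """Given all metrics at high precision, the search recovers the matrix."""
    cm = ConfusionMatrix(tp, fp, fn, tn)
    m = compute_metrics(cm)
    reported = {
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "ppv": m.ppv, "npv": m.npv, "fp_rate_total": m.fp_rate_total,
        "fn_rate_total": m.fn_rate_total, "prevalence": m.prevalence,
    }
    reported = {k: round(v, 4) for k, v in reported.items() if v is not None}
    result = reconstruct_confusion_matrix(reported, n=cm.n, decimals=4)
    assert result.best is not None
    assert result.best.as_tuple() == cm.as_tuple()


def test_reconstruction_input_validation():
    with pytest.raises(ValueError, match="exactly one"):
        reconstruct_confusion_matrix({"sensitivity": 50.0})
    with pytest.raises(ValueError, match="unknown metric"):
        reconstruct_confusion_matrix({"sens": 50.0}, n=10)
    with pytest.raises(ValueError, match="2000"):
        reconstruct_confusion_matrix({"sensitivity": 50.0}, n_max=5000)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def test_evaluation_report_structure(tiny_cohort):
    report = evaluation_report(tiny_cohort)
    assert set(report["rules"]) == {"ratio_only", "dflc_only", "combined"}
    combined = report["rules"]["combined"]
    assert "matrix" in combined and "metrics" in combined
    m = combined["metrics"]
    # both FN conventions co-reported
    assert "fn_rate_total" in m and "fnr_of_positives" in m
    assert "targets_met" in combined
    text = report_markdown(report)
    assert "Rule: combined" in text


def test_report_without_truth_degrades_gracefully():
    from bjscreen.cohort import Cohort, SampleRecord
    cohort = Cohort(records=[SampleRecord("a", "a", 10.0, 10.0),
                             SampleRecord("b", "b", 600.0, 5.0)])
    report = evaluation_report(cohort)
    assert "notice" in report
    assert "metrics" not in report["rules"]["combined"]
    assert report["rules"]["combined"]["avoided_fraction"] == 0.5


def test_cohort_realizing_matrix_reproduces_counts():
    cm = ConfusionMatrix(7, 3, 2, 8)
    cohort = cohort_realizing_matrix(cm)
    from bjscreen.ruleout import screen_positive_series
    screen = screen_positive_series(cohort)
    truths = pd.Series({r.sample_id: r.uife_result for r in cohort})
    assert confusion_matrix(screen, truths).as_tuple() == cm.as_tuple()


def test_screening_targets_validation():
    with pytest.raises(ValueError):
        ScreeningTargets(min_sensitivity=0)
    targets = ScreeningTargets()
    assert (targets.min_sensitivity, targets.max_fn) == (85.0, 5.0)
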