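"""ROC construction, Youden cutoff selection, and cohort derivations.

The AUC is cross-checked against an independent Mann-Whitney pair-counting
oracle, and the Youden selection against exhaustive search.
"""

import dataclasses

import numpy as np
import pytest

from bjscreen.cohort import Cohort, SampleRecord
from bjscreen.cutoffs import (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE,
                              build_roc, derive_dflc_cutoff,
                              derive_ratio_cutoffs, derive_uprotein_cutoff,
                              roc_to_frame, youden_cutoff)
from bjscreen.errors import RocUndefinedError
from bjscreen.simulate import LogNormal, SimulatorParams, generate_cohort


def pair_count_auc(values, labels):
    """Mann-Whitney concordance probability with 0.5 credit for ties."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = values[labels]
    neg = values[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(values, labels, higher=True):
    """Best J over every threshold between distinct values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    distinct = np.unique(values)
    candidates = np.concatenate((
        [distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0
        if distinct.size > 1 else [], [distinct[-1] + 1.0],
    ))
    best_j = -np.inf
    for t in candidates:
        pred = values > t if higher else values < t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


def test_perfect_separation_auc():
    roc = build_roc([1, 2, 3, 4], [False, False, True, True])
    assert roc.auc == pytest.approx(1.0)


def test_interleaved_auc_matches_pair_counting():
    values = [1, 2, 3, 4]
    labels = [True, False, True, False]
    roc = build_roc(values, labels)
    assert roc.auc == pytest.approx(0.25)
    assert roc.auc == pytest.approx(pair_count_auc(values, labels))


def test_all_tied_values_auc_half():
    roc = build_roc([5, 5, 5, 5], [True, False, True, False])
    assert roc.auc == pytest.approx(0.5)


def test_single_class_labels_rejected():
    with pytest.raises(RocUndefinedError, match="ROC undefined"):
        build_roc([1, 2, 3], [True, True, True])


def test_auc_equals_mann_whitney_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = rng.integers(4, 12)
        values = rng.integers(0, 6, n).astype(float)  # integer-valued: ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        roc = build_roc(values, labels)
        assert roc.auc == pytest.approx(pair_count_auc(values, labels),
                                        abs=1e-12)


def test_direction_reversal_flips_auc():
    rng = np.random.default_rng(7)
    values = rng.normal(size=30)
    labels = rng.random(30) < 0.4
    hi = build_roc(values, labels, HIGHER_IS_POSITIVE)
    lo = build_roc(values, labels, LOWER_IS_POSITIVE)
    assert hi.auc + lo.auc == pytest.approx(1.0)


def test_youden_equals_exhaustive_search():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = rng.integers(5, 15)
        values = rng.integers(0, 8, n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        result = youden_cutoff(build_roc(values, labels))
        assert result.youden_j == pytest.approx(
            brute_force_youden(values, labels), abs=1e-12
        )


def test_youden_example_by_brute_force():
    values = [1, 2, 3, 4, 5]
    labels = [False, False, True, False, True]
    result = youden_cutoff(build_roc(values, labels))
    assert result.youden_j == pytest.approx(
        brute_force_youden(values, labels)
    )


def test_perfectly_separated_cutoff_is_midpoint():
    result = youden_cutoff(build_roc([1, 2, 3, 50, 60],
                                     [False] * 3 + [True] * 2))
    assert result.youden_j == pytest.approx(1.0)
    assert result.cutoff == pytest.approx((3 + 50) / 2)


def test_degenerate_all_ties_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        result = youden_cutoff(build_roc([2, 2, 2], [True, False, True]))
    assert result.youden_j == pytest.approx(0.0)
    assert result.degenerate


def test_roc_points_monotone_and_exportable():
    rng = np.random.default_rng(5)
    values = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    roc = build_roc(values, labels)
    frame = roc_to_frame(roc)
    assert list(frame.columns) == ["threshold", "sensitivity", "specificity"]
    # tightening the positivity criterion can only lower sensitivity
    assert (frame["threshold"].diff().dropna() > 0).all()
    assert (frame["sensitivity"].diff().dropna() <= 1e-12).all()


# ---------------------------------------------------------------------------
# Cohort derivations
# ---------------------------------------------------------------------------


def _toy_cohort():
    """3 negatives with small dFLC, 2 kappa clones with large dFLC."""
    recs = []
    for i, (k, l, uife) in enumerate([
        (11.0, 10.0, "negative"), (12.0, 10.0, "negative"),
        (13.0, 10.0, "negative"), (60.0, 10.0, "kappa_bjp"),
        (70.0, 10.0, "kappa_bjp"),
    ]):
        recs.append(SampleRecord(f"s{i}", f"p{i}", k, l, 0.1, uife))
    return Cohort(records=recs)


def test_dflc_derivation_on_separated_toy_set():
    result = derive_dflc_cutoff(_toy_cohort())
    assert result.youden_j == pytest.approx(1.0)
    assert 3 < result.cutoff < 50
    assert result.direction == HIGHER_IS_POSITIVE


def test_dflc_derivation_requires_cases():
    recs = [SampleRecord(f"s{i}", f"p{i}", 10.0, 10.0, 0.1, "negative")
            for i in range(5)]
    with pytest.raises(RocUndefinedError):
        derive_dflc_cutoff(Cohort(records=recs))


def test_uprotein_derivation_excludes_missing_and_handles_ties():
    recs = [SampleRecord(f"s{i}", f"p{i}", 10.0, 10.0, 0.5,
                         "negative" if i < 3 else "kappa_bjp")
            for i in range(6)]
    # one record without urine protein is excluded, not fatal
    recs.append(SampleRecord("s9", "p9", 10.0, 10.0, None, "negative"))
    with pytest.warns(UserWarning):
        result = derive_uprotein_cutoff(Cohort(records=recs))
    assert result.auc == pytest.approx(0.5)
    assert result.at_cutoff.n == 6


def test_ratio_sides_absent_without_cases():
    recs = [SampleRecord(f"s{i}", f"p{i}", 500.0 if i < 2 else 10.0, 10.0,
                         0.1, "kappa_bjp" if i < 2 else "negative")
            for i in range(5)]
    sided = derive_ratio_cutoffs(Cohort(records=recs))
    assert sided.lambda_side is None
    assert sided.kappa_side is not None
    assert any("lambda_side" in note for note in sided.notes)


def test_control_policy_changes_control_set(tiny_cohort):
    negatives_only = derive_ratio_cutoffs(tiny_cohort, "uife_negative_only")
    all_non_case = derive_ratio_cutoffs(tiny_cohort, "all_non_case")
    assert negatives_only.kappa_side.at_cutoff.n == 5  # 2 cases + 3 controls
    assert all_non_case.kappa_side.at_cutoff.n == 6    # lambda case joins


def test_dflc_boundary_recovery():
    """A generated cohort whose urinary appearance switches at dFLC ~ 12
    mg/L yields a derived cutoff within 2 mg/L of the boundary."""
    params = SimulatorParams(
        n=5000, p_kappa_clone=0.31, p_lambda_clone=0.205,
        polyclonal_kappa=LogNormal(12.0, 0.05),
        polyclonal_lambda=LogNormal(12.0, 0.05),
        polyclonal_common_sigma=0.0,
        monoclonal_kappa=LogNormal(24.0, 1.0),
        monoclonal_lambda=LogNormal(24.0, 1.0),
        reabsorption_capacity_kappa=24.0,
        reabsorption_capacity_lambda=24.0,
        egfr_scaling=False, appearance_noise_width=0.0,
        measurement_cv=0.0, seed=7,
    )
    result = derive_dflc_cutoff(generate_cohort(params))
    assert result.cutoff == pytest.approx(12.0, abs=2.0)


def test_lambda_ratio_boundary_recovery():
    """With polyclonal kappa pinned at 12 and lambda spilling above 15
    mg/L, the latent lambda decision boundary sits at ratio 12/15 = 0.8."""
    params = SimulatorParams(
        n=5000, p_kappa_clone=0.0, p_lambda_clone=0.5,
        polyclonal_kappa=LogNormal(12.0, 0.01),
        polyclonal_lambda=LogNormal(12.0, 0.01),
        polyclonal_common_sigma=0.0,
        monoclonal_lambda=LogNormal(3.0, 1.0),
        reabsorption_capacity_lambda=15.0,
        egfr_scaling=False, appearance_noise_width=0.0,
        measurement_cv=0.0, seed=7,
    )
    sided = derive_ratio_cutoffs(generate_cohort(params))
    assert sided.lambda_side.cutoff == pytest.approx(0.8, abs=0.1)
    assert sided.lambda_side.direction == LOWER_IS_POSITIVE
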