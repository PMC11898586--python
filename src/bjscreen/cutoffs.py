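"""ROC construction and optimal rule-out cutoff derivation.

The ratio is a two-sided marker — abnormally high suggests a kappa clone,
abnormally low a lambda clone — so cutoffs are derived from two one-sided
ROC analyses (``lower_is_positive`` for the lambda side,
``higher_is_positive`` for the kappa side).  dFLC and urine total protein
are one-sided markers with ``higher_is_positive``.

Cutoff selection maximizes Youden's J = sensitivity + specificity - 1 over
candidate thresholds placed at midpoints between adjacent distinct observed
values, so the reported cutoff never coincides with a datum.  Ties in J are
broken toward higher specificity (fewer urine tests), then toward the more
extreme threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import Cohort, UIFE_KAPPA, UIFE_LAMBDA, UIFE_NEGATIVE
from .errors import RocUndefinedError, UndefinedRatioError
from .evaluation import ConfusionMatrix, DiagnosticMetrics, compute_metrics
from .markers import compute_markers

logger = logging.getLogger(__name__)

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"

CONTROL_UIFE_NEGATIVE_ONLY = "uife_negative_only"
CONTROL_ALL_NON_CASE = "all_non_case"


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocCurve:
    """ROC points (ordered by threshold), trapezoidal AUC, and raw data."""

    points: list[RocPoint]
    auc: float
    direction: str
    values: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


@dataclass
class CutoffResult:
    """An optimal operating point with its at-cutoff diagnostic metrics."""

    cutoff: float
    auc: float
    at_cutoff: DiagnosticMetrics
    direction: str
    case_definition: str = ""
    control_definition: str = ""
    youden_j: float = float("nan")
    degenerate: bool = False


def build_roc(
    values: Sequence[float],
    labels: Sequence[bool],
    direction: str = HIGHER_IS_POSITIVE,
) -> RocCurve:
    """ROC curve of a marker against binary truth.

    Thresholds are enumerated at every distinct observed value (ties
    grouped) plus an all-positive infinity endpoint; the AUC is the
    trapezoidal area, which on the same data equals the Mann–Whitney
    concordance probability.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("marker values must be finite")
    if labels.all() or not labels.any():
        raise RocUndefinedError(
            "ROC undefined: need at least one case and one control"
        )
    if direction not in (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")

    score = values if direction == HIGHER_IS_POSITIVE else -values
    fpr, tpr, thr = _sk_roc_curve(labels, score)
    area = float(_trapezoid_auc(fpr, tpr))
    points = []
    for f, t, s in zip(fpr, tpr, thr):
        threshold = float(s) if direction == HIGHER_IS_POSITIVE else float(-s)
        points.append(RocPoint(threshold=threshold, sensitivity=float(t),
                               specificity=float(1.0 - f)))
    points.sort(key=lambda p: p.threshold)
    return RocCurve(points=points, auc=area, direction=direction,
                    values=values, labels=labels)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values plus outside endpoints."""
    distinct = np.unique(values)
    if distinct.size == 1:
        pad = max(abs(distinct[0]), 1.0)
        return np.array([distinct[0] - pad, distinct[0] + pad])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    pad = (distinct[-1] - distinct[0]) / 2.0
    return np.concatenate(([distinct[0] - pad], mids, [distinct[-1] + pad]))


def youden_cutoff(
    roc: RocCurve, case_definition: str = "", control_definition: str = ""
) -> CutoffResult:
    """Operating point maximizing Youden's J on an ROC curve.

    Screen-positive means value strictly beyond the cutoff in the curve's
    direction.  With all marker values tied the curve is degenerate: J = 0
    and the result is flagged with a warning.
    """
    values, labels = roc.values, roc.labels
    higher = roc.direction == HIGHER_IS_POSITIVE
    pos_total = int(labels.sum())
    neg_total = int((~labels).sum())

    best = None  # (J, specificity, extreme_key, threshold, cm)
    for t in _candidate_thresholds(values):
        pred = values > t if higher else values < t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        sens = tp / pos_total
        spec = (neg_total - fp) / neg_total
        j = sens + spec - 1.0
        extreme = t if higher else -t
        key = (j, spec, extreme)
        if best is None or key > best[0]:
            cm = ConfusionMatrix(tp=tp, fp=fp, fn=pos_total - tp,
                                 tn=neg_total - fp)
            best = (key, t, j, cm)

    _, threshold, j, cm = best
    degenerate = np.unique(values).size == 1
    if degenerate:
        warnings.warn(
            "all marker values are tied: ROC is degenerate, J = 0",
            stacklevel=2,
        )
    return CutoffResult(
        cutoff=float(threshold), auc=roc.auc, at_cutoff=compute_metrics(cm),
        direction=roc.direction, case_definition=case_definition,
        control_definition=control_definition, youden_j=float(j),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Cohort-level derivations
# ---------------------------------------------------------------------------


def _marker_arrays(cohort: Cohort, marker: str) -> pd.DataFrame:
    """Per-sample marker value + uIFE truth, skipping unusable records."""
    rows = []
    skipped_ratio = 0
    skipped_missing = 0
    for record in cohort:
        if record.uife_result is None:
            continue
        if marker == "urine_total_protein":
            if record.urine_total_protein is None:
                skipped_missing += 1
                continue
            value = record.urine_total_protein
        else:
            try:
                panel = compute_markers(record)
            except UndefinedRatioError:
                skipped_ratio += 1
                continue
            value = getattr(panel, marker)
        rows.append({"sample_id": record.sample_id, "value": value,
                     "uife": record.uife_result})
    if skipped_missing:
        logger.info("derive: excluded %d records missing %s",
                    skipped_missing, marker)
    if skipped_ratio:
        logger.info("derive: excluded %d records with undefined ratio",
                    skipped_ratio)
    return pd.DataFrame(rows, columns=["sample_id", "value", "uife"])


def _derive_one_sided(
    frame: pd.DataFrame, case_levels: set, control_levels: set,
    direction: str, case_definition: str, control_definition: str,
) -> Optional[CutoffResult]:
    used = frame[frame["uife"].isin(case_levels | control_levels)]
    labels = used["uife"].isin(case_levels).to_numpy()
    if not labels.any() or labels.all():
        return None
    roc = build_roc(used["value"].to_numpy(), labels, direction)
    return youden_cutoff(roc, case_definition, control_definition)


@dataclass
class SidedCutoffs:
    """Two-sided ratio derivation: one cutoff per clone type."""

    lambda_side: Optional[CutoffResult]
    kappa_side: Optional[CutoffResult]
    notes: list[str] = field(default_factory=list)


def derive_ratio_cutoffs(
    cohort: Cohort, control_policy: str = CONTROL_UIFE_NEGATIVE_ONLY
) -> SidedCutoffs:
    """Derive the lambda-side (<) and kappa-side (>) ratio cutoffs.

    Cases for each side are that clone's uIFE-positive samples.  Controls
    are uIFE-negative samples under the default policy; the
    ``all_non_case`` policy additionally counts opposite-clone samples as
    controls.
    """
    if control_policy not in (CONTROL_UIFE_NEGATIVE_ONLY, CONTROL_ALL_NON_CASE):
        raise ValueError(f"unknown control policy {control_policy!r}")
    frame = _marker_arrays(cohort, "ratio")
    notes = []
    results = {}
    for side, case_level, direction in (
        ("lambda_side", UIFE_LAMBDA, LOWER_IS_POSITIVE),
        ("kappa_side", UIFE_KAPPA, HIGHER_IS_POSITIVE),
    ):
        controls = {UIFE_NEGATIVE}
        if control_policy == CONTROL_ALL_NON_CASE:
            controls |= {UIFE_KAPPA, UIFE_LAMBDA} - {case_level}
        result = _derive_one_sided(
            frame, {case_level}, controls, direction,
            case_definition=f"uIFE {case_level}",
            control_definition=f"controls: {sorted(controls)}",
        )
        if result is None:
            notes.append(
                f"{side}: no usable cases or controls "
                f"(cases = uIFE {case_level}); cutoff absent"
            )
        results[side] = result
    return SidedCutoffs(lambda_side=results["lambda_side"],
                        kappa_side=results["kappa_side"], notes=notes)


def derive_dflc_cutoff(cohort: Cohort) -> CutoffResult:
    """dFLC cutoff: cases = any BJP clone, controls = uIFE-negative."""
    frame = _marker_arrays(cohort, "dflc")
    result = _derive_one_sided(
        frame, {UIFE_KAPPA, UIFE_LAMBDA}, {UIFE_NEGATIVE},
        HIGHER_IS_POSITIVE, "uIFE BJP (kappa or lambda)",
        "uIFE negative",
    )
    if result is None:
        raise RocUndefinedError(
            "dFLC cutoff derivation needs both BJP cases and uIFE-negative "
            "controls"
        )
    return result


def derive_uprotein_cutoff(cohort: Cohort) -> CutoffResult:
    """Urine total protein cutoff; records missing the marker are excluded."""
    frame = _marker_arrays(cohort, "urine_total_protein")
    result = _derive_one_sided(
        frame, {UIFE_KAPPA, UIFE_LAMBDA}, {UIFE_NEGATIVE},
        HIGHER_IS_POSITIVE, "uIFE BJP (kappa or lambda)",
        "uIFE negative",
    )
    if result is None:
        raise RocUndefinedError(
            "urine protein cutoff derivation needs both cases and controls"
        )
    return result


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------


def roc_to_frame(roc: RocCurve) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.threshold, p.sensitivity, p.specificity) for p in roc.points],
        columns=["threshold", "sensitivity", "specificity"],
    )


def cutoff_to_dict(result: CutoffResult) -> dict:
    return {
        "cutoff": result.cutoff,
        "auc": result.auc,
        "direction": result.direction,
        "youden_j": result.youden_j,
        "degenerate": result.degenerate,
        "case_definition": result.case_definition,
        "control_definition": result.control_definition,
        "at_cutoff": result.at_cutoff.as_dict(),
    }


def plot_roc(roc: RocCurve, path, title: str = "ROC") -> None:
    """Write an ROC plot (sensitivity vs 1-specificity) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [1.0 - p.specificity for p in roc.points]
    tpr = [p.sensitivity for p in roc.points]
    order = np.argsort(fpr)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order], marker=".",
            label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
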