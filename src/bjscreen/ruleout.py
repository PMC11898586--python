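"""The sFLC rule-out decision algorithm and single-marker screening rules.

A sample is ruled out (no urine work-up needed) when its kappa/lambda ratio
lies inside the rule-out window AND its dFLC is below the dFLC bound.
Everything else — including samples whose ratio cannot be computed — is sent
to urine testing.  Screen positive always means "urine testing indicated".

Two threshold presets ship with the package: the validated deployment values
(ratio 0.8–2, dFLC < 12 mg/L, the default) and the original derivation
values (0.82, 1.99, 11.93 mg/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .cohort import Cohort, SampleRecord
from .errors import UndefinedRatioError
from .markers import (DEFAULT_REFERENCE, MarkerPanel, ReferenceRange,
                      compute_markers)

RULE_OUT = "RULE_OUT"
URINE_TEST_INDICATED = "URINE_TEST_INDICATED"


@dataclass(frozen=True)
class RuleoutThresholds:
    """Operating thresholds of the combined rule-out screen.

    The ratio window is inclusive and the dFLC bound strict by default,
    reading "ratio 0.8–2 and dFLC < 12" literally; both conventions are
    flags so a site can tighten them.
    """

    ratio_low: float = 0.8
    ratio_high: float = 2.0
    dflc_max: float = 12.0
    ratio_bounds_inclusive: bool = True
    dflc_bound_strict: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ratio_low < self.ratio_high):
            raise ValueError(
                f"need 0 < ratio_low < ratio_high, got "
                f"({self.ratio_low}, {self.ratio_high})"
            )
        if not self.dflc_max > 0:
            raise ValueError(f"dflc_max must be positive, got {self.dflc_max}")

    def ratio_in_window(self, ratio: float) -> bool:
        if self.ratio_bounds_inclusive:
            return self.ratio_low <= ratio <= self.ratio_high
        return self.ratio_low < ratio < self.ratio_high

    def dflc_below(self, dflc: float) -> bool:
        return dflc < self.dflc_max if self.dflc_bound_strict \
            else dflc <= self.dflc_max


#: thresholds validated on the external cohort; the deployed defaults
VALIDATION_PRESET = RuleoutThresholds(0.8, 2.0, 12.0)
#: exact ROC-derived thresholds from the derivation cohort
DERIVATION_PRESET = RuleoutThresholds(0.82, 1.99, 11.93)

_PRESETS = {"validation": VALIDATION_PRESET, "derivation": DERIVATION_PRESET}


def thresholds_preset(name: str) -> RuleoutThresholds:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown thresholds preset {name!r}; known: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Decision:
    """Per-sample verdict; ``triggered_by`` lists the criteria that failed."""

    verdict: str
    triggered_by: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.verdict == RULE_OUT) != (len(self.triggered_by) == 0):
            raise ValueError("RULE_OUT iff no triggered criteria")


def classify_sample(
    panel: MarkerPanel, thresholds: RuleoutThresholds = VALIDATION_PRESET
) -> Decision:
    """Apply the combined rule to one marker panel."""
    triggered = []
    if not thresholds.ratio_in_window(panel.ratio):
        side = "high" if panel.ratio > thresholds.ratio_high else "low"
        triggered.append(f"ratio {side}")
    if not thresholds.dflc_below(panel.dflc):
        triggered.append("dflc high")
    if triggered:
        return Decision(URINE_TEST_INDICATED, tuple(triggered))
    return Decision(RULE_OUT)


def classify_record(
    record: SampleRecord,
    thresholds: RuleoutThresholds = VALIDATION_PRESET,
    ref: ReferenceRange = DEFAULT_REFERENCE,
) -> Decision:
    """Classify a raw record; an uncomputable ratio is never ruled out."""
    try:
        panel = compute_markers(record, ref)
    except UndefinedRatioError:
        return Decision(URINE_TEST_INDICATED, ("ratio undefined",))
    return classify_sample(panel, thresholds)


# ---------------------------------------------------------------------------
# Single-marker screening rules
# ---------------------------------------------------------------------------

MARKER_URINE_PROTEIN = "urine_total_protein"
MARKER_RATIO_LOWER = "ratio_lower_tail"
MARKER_RATIO_UPPER = "ratio_upper_tail"
MARKER_DFLC = "dflc"

_MARKERS = (MARKER_URINE_PROTEIN, MARKER_RATIO_LOWER, MARKER_RATIO_UPPER,
            MARKER_DFLC)


@dataclass(frozen=True)
class SingleMarkerRule:
    """One-marker screen: positive when the marker crosses the cutoff.

    ``ratio_lower_tail`` is positive below the cutoff (lambda clone
    detection); the other markers are positive above it.
    """

    marker: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.marker not in _MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; known: {_MARKERS}")
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


def apply_single_marker_rule(
    subject: Union[MarkerPanel, SampleRecord],
    rule: SingleMarkerRule,
    ref: ReferenceRange = DEFAULT_REFERENCE,
) -> bool:
    """Binary screen result of a single-marker rule (True = positive)."""
    if rule.marker == MARKER_URINE_PROTEIN:
        if not isinstance(subject, SampleRecord):
            raise ValueError(
                "urine_total_protein rules need a SampleRecord, not a panel"
            )
        if subject.urine_total_protein is None:
            raise ValueError(
                f"sample {subject.sample_id!r}: marker urine_total_protein "
                "is missing"
            )
        return subject.urine_total_protein > rule.cutoff
    panel = compute_markers(subject, ref) if isinstance(subject, SampleRecord) \
        else subject
    if rule.marker == MARKER_RATIO_LOWER:
        return panel.ratio < rule.cutoff
    if rule.marker == MARKER_RATIO_UPPER:
        return panel.ratio > rule.cutoff
    return panel.dflc > rule.cutoff


# ---------------------------------------------------------------------------
# Cohort-level classification
# ---------------------------------------------------------------------------


@dataclass
class CohortDecisions:
    """Per-sample decisions joinable by sample_id, plus avoided-test count."""

    decisions: pd.DataFrame  # columns: sample_id, verdict, triggered_by
    avoided_count: int
    total: int

    @property
    def avoided_fraction(self) -> float:
        return self.avoided_count / self.total


def screen_positive_series(
    cohort: Cohort,
    thresholds: RuleoutThresholds = VALIDATION_PRESET,
    rule: str = "combined",
    ref: ReferenceRange = DEFAULT_REFERENCE,
) -> pd.Series:
    """Boolean screen-positive series indexed by sample_id.

    ``rule`` is ``combined`` (the deployed conjunction), ``ratio_only``
    (positive when the ratio leaves the window) or ``dflc_only`` (positive
    when dFLC reaches the bound).  Samples with an undefined ratio are
    positive under every rule (fail-safe).
    """
    if rule not in ("combined", "ratio_only", "dflc_only"):
        raise ValueError(f"unknown rule {rule!r}")
    out = {}
    for record in cohort:
        try:
            panel = compute_markers(record, ref)
        except UndefinedRatioError:
            out[record.sample_id] = True
            continue
        ratio_bad = not thresholds.ratio_in_window(panel.ratio)
        dflc_bad = not thresholds.dflc_below(panel.dflc)
        if rule == "ratio_only":
            out[record.sample_id] = ratio_bad
        elif rule == "dflc_only":
            out[record.sample_id] = dflc_bad
        else:
            out[record.sample_id] = ratio_bad or dflc_bad
    return pd.Series(out, dtype=bool)


def classify_cohort(
    cohort: Cohort,
    thresholds: RuleoutThresholds = VALIDATION_PRESET,
    ref: ReferenceRange = DEFAULT_REFERENCE,
) -> CohortDecisions:
    """Apply the combined rule to every sample of a cohort."""
    rows = []
    for record in cohort:
        decision = classify_record(record, thresholds, ref)
        rows.append({
            "sample_id": record.sample_id,
            "verdict": decision.verdict,
            "triggered_by": ";".join(decision.triggered_by),
        })
    frame = pd.DataFrame(rows, columns=["sample_id", "verdict", "triggered_by"])
    avoided = int((frame["verdict"] == RULE_OUT).sum())
    return CohortDecisions(decisions=frame, avoided_count=avoided,
                           total=len(cohort))


@dataclass(frozen=True)
class Savings:
    hours: float
    cost: float


def estimate_savings(
    avoided_count: int, time_per_test: float, cost_per_test: float
) -> Savings:
    """Workload saved by the rule-outs, from user-supplied unit values."""
    if avoided_count < 0 or time_per_test < 0 or cost_per_test < 0:
        raise ValueError("savings inputs must be non-negative")
    return Savings(hours=avoided_count * time_per_test,
                   cost=avoided_count * cost_per_test)
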