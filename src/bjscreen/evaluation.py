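"""2x2 diagnostic evaluation against urine immunofixation truth.

Orientation is fixed package-wide: *screen positive* means urine testing is
indicated (marker abnormal / not ruled out); *truth positive* means uIFE
found Bence Jones protein.  A false negative is therefore a BJP-positive
sample that the screen ruled out — the clinically costly error.

Two false-negative conventions coexist in screening reports and are both
first-class here:

* ``fn_rate_total``      = fn / n          (share of the whole cohort)
* ``fnr_of_positives``   = fn / (tp + fn)  (complement of sensitivity)

All rate metrics are reported on the percent scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import UIFE_NEGATIVE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts under the fixed screen/truth orientation."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its large-sample standard error and 95% CI."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Full metric suite for one 2x2 table; undefined metrics are None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fp_rate_total: float
    fn_rate_total: float
    fnr_of_positives: Optional[float]
    prevalence: float
    kappa: Optional[KappaResult]
    n: int
    reasons: Mapping[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "fp_rate_total": self.fp_rate_total,
            "fn_rate_total": self.fn_rate_total,
            "fnr_of_positives": self.fnr_of_positives,
            "prevalence": self.prevalence,
        }
        if self.kappa is not None:
            out["kappa"] = self.kappa.kappa
            out["kappa_se"] = self.kappa.se
            out["kappa_ci_95"] = [self.kappa.ci_low, self.kappa.ci_high]
        if self.reasons:
            out["undefined"] = dict(self.reasons)
        return out


@dataclass(frozen=True)
class ScreeningTargets:
    """Minimum performance demanded of a rule-out screen.

    ``max_fn`` is checked against ``fn_rate_total`` (false negatives as a
    share of all samples screened); the report co-prints the per-positive
    convention so the reader can apply either.
    """

    min_sensitivity: float = 85.0
    max_fn: float = 5.0

    def __post_init__(self) -> None:
        for name in ("min_sensitivity", "max_fn"):
            value = getattr(self, name)
            if not (0 < value < 100):
                raise ValueError(f"{name} must be in (0, 100), got {value}")


def confusion_matrix(
    screen_positive: pd.Series, truths: pd.Series
) -> ConfusionMatrix:
    """Cross-tabulate screen results against uIFE truth.

    Both inputs are indexed by ``sample_id``.  ``screen_positive`` is boolean
    (urine testing indicated); ``truths`` holds uIFE levels.  Records with a
    missing truth are excluded with a logged count; a screen result without a
    matching truth index (or vice versa) is an alignment error.
    """
    screen_positive = pd.Series(screen_positive)
    truths = pd.Series(truths)
    if set(screen_positive.index) != set(truths.index):
        only_screen = set(screen_positive.index) - set(truths.index)
        only_truth = set(truths.index) - set(screen_positive.index)
        raise ValueError(
            "screen results and truths are not aligned by sample_id "
            f"(screen-only: {sorted(only_screen)[:5]}, "
            f"truth-only: {sorted(only_truth)[:5]})"
        )
    truths = truths.reindex(screen_positive.index)
    usable = truths.notna()
    dropped = int((~usable).sum())
    if dropped:
        logger.info("confusion_matrix: excluded %d records without uIFE truth",
                    dropped)
    if usable.sum() == 0:
        raise ValueError("no records with uIFE truth available")
    screen = screen_positive[usable].astype(bool)
    truth_pos = truths[usable] != UIFE_NEGATIVE
    return ConfusionMatrix(
        tp=int((screen & truth_pos).sum()),
        fp=int((screen & ~truth_pos).sum()),
        fn=int((~screen & truth_pos).sum()),
        tn=int((~screen & ~truth_pos).sum()),
    )


def cohen_kappa(cm: ConfusionMatrix) -> Optional[KappaResult]:
    """Cohen's kappa for screen/truth agreement.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp + tn)/n and chance agreement p_e from the marginal products.
    The standard error is the classical large-sample form
    sqrt(p_o (1 - p_o) / n) / (1 - p_e); the CI is kappa +/- 1.96 SE.
    Returns None when the marginals are degenerate (p_e = 1).
    """
    n = cm.n
    p_o = (cm.tp + cm.tn) / n
    screen_pos = (cm.tp + cm.fp) / n
    truth_pos = (cm.tp + cm.fn) / n
    p_e = screen_pos * truth_pos + (1 - screen_pos) * (1 - truth_pos)
    if p_e >= 1.0:
        return None
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(max(p_o * (1 - p_o), 0.0) / n) / (1 - p_e)
    return KappaResult(
        kappa=kappa, se=se, ci_low=kappa - 1.96 * se, ci_high=kappa + 1.96 * se
    )


def compute_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """All diagnostic metrics of a 2x2 table, on the percent scale."""
    n = cm.n
    reasons: dict[str, str] = {}

    def ratio_pct(num: int, den: int, name: str, reason: str) -> Optional[float]:
        if den == 0:
            reasons[name] = reason
            return None
        return 100.0 * num / den

    sens = ratio_pct(cm.tp, cm.tp + cm.fn, "sensitivity", "no truth positives")
    spec = ratio_pct(cm.tn, cm.tn + cm.fp, "specificity", "no truth negatives")
    ppv = ratio_pct(cm.tp, cm.tp + cm.fp, "ppv", "no screen positives")
    npv = ratio_pct(cm.tn, cm.tn + cm.fn, "npv", "no screen negatives")
    fnr = ratio_pct(cm.fn, cm.tp + cm.fn, "fnr_of_positives",
                    "no truth positives")
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        fp_rate_total=100.0 * cm.fp / n,
        fn_rate_total=100.0 * cm.fn / n,
        fnr_of_positives=fnr,
        prevalence=100.0 * (cm.tp + cm.fn) / n,
        kappa=cohen_kappa(cm),
        n=n,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Integer reconstruction of a 2x2 table from published percentages
# ---------------------------------------------------------------------------

#: metric name -> (numerator, denominator) as functions of (tp, fp, fn, tn, n)
_METRIC_DEFS = {
    "sensitivity": lambda tp, fp, fn, tn, n: (tp, tp + fn),
    "specificity": lambda tp, fp, fn, tn, n: (tn, tn + fp),
    "ppv": lambda tp, fp, fn, tn, n: (tp, tp + fp),
    "npv": lambda tp, fp, fn, tn, n: (tn, tn + fn),
    "fp_rate_total": lambda tp, fp, fn, tn, n: (fp, n),
    "fn_rate_total": lambda tp, fp, fn, tn, n: (fn, n),
    "fnr_of_positives": lambda tp, fp, fn, tn, n: (fn, tp + fn),
    "prevalence": lambda tp, fp, fn, tn, n: (tp + fn, n),
}


@dataclass(frozen=True)
class ReconstructionCandidate:
    matrix: ConfusionMatrix
    deviation: float  # sum of squared differences from the reported metrics


@dataclass
class ReconstructionResult:
    """Outcome of the exhaustive integer 2x2 search."""

    candidates: list[ReconstructionCandidate]
    closest: Optional[ReconstructionCandidate]  # best even if out of tolerance
    reported: dict
    tolerance: float

    @property
    def best(self) -> Optional[ConfusionMatrix]:
        return self.candidates[0].matrix if self.candidates else None

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1


def _metric_pct(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, 100.0 * num / den, np.nan)


def reconstruct_confusion_matrix(
    reported: Mapping[str, float],
    n: Optional[int] = None,
    n_max: Optional[int] = None,
    decimals: int = 2,
) -> ReconstructionResult:
    """Exhaustively search integer 2x2 tables matching published percentages.

    ``reported`` maps metric names (keys of the metric registry:
    sensitivity, specificity, ppv, npv, fp_rate_total, fn_rate_total,
    fnr_of_positives, prevalence) to printed percent values.  Either ``n``
    (total fixed) or ``n_max`` (search all totals up to the bound) must be
    given.  A candidate matches when every reported metric agrees within one
    unit in the last printed decimal place — published tables may round or
    truncate, so the band is a full ulp, ``10**-decimals``.

    Candidates are ranked by total squared deviation from the reported
    values, then lexicographically by (tp, fp, fn, tn), so the ordering is
    deterministic.  When nothing falls inside the tolerance the candidate
    list is empty and ``closest`` reports the nearest miss.
    """
    if (n is None) == (n_max is None):
        raise ValueError("specify exactly one of n and n_max")
    if n_max is not None and n_max > 2000:
        raise ValueError("n_max above 2000 is not supported")
    unknown = set(reported) - set(_METRIC_DEFS)
    if unknown:
        raise ValueError(f"unknown metric names: {sorted(unknown)}")
    if not reported:
        raise ValueError("at least one reported metric is required")
    tol = 10.0 ** (-decimals)
    n_values = [n] if n is not None else range(1, n_max + 1)

    sens = reported.get("sensitivity")
    fnr = reported.get("fnr_of_positives")
    spec = reported.get("specificity")

    matches: list[ReconstructionCandidate] = []
    closest: Optional[ReconstructionCandidate] = None

    for n_i in n_values:
        for pos in range(0, n_i + 1):
            neg = n_i - pos
            # prune tp by sensitivity / per-positive FN rate when available
            tp_arr = np.arange(pos + 1)
            if pos > 0:
                if sens is not None:
                    tp_arr = tp_arr[
                        np.abs(_metric_pct(tp_arr, np.full_like(tp_arr, pos))
                               - sens) <= tol + 1e-12
                    ]
                if fnr is not None and tp_arr.size:
                    tp_arr = tp_arr[
                        np.abs(_metric_pct(pos - tp_arr,
                                           np.full_like(tp_arr, pos))
                               - fnr) <= tol + 1e-12
                    ]
            elif sens is not None or fnr is not None:
                continue  # metric reported but undefined at pos = 0
            if tp_arr.size == 0:
                continue
            tn_arr = np.arange(neg + 1)
            if neg > 0:
                if spec is not None:
                    tn_arr = tn_arr[
                        np.abs(_metric_pct(tn_arr, np.full_like(tn_arr, neg))
                               - spec) <= tol + 1e-12
                    ]
            elif spec is not None:
                continue
            if tn_arr.size == 0:
                continue

            tp_g, tn_g = np.meshgrid(tp_arr, tn_arr, indexing="ij")
            tp_f = tp_g.ravel()
            tn_f = tn_g.ravel()
            fn_f = pos - tp_f
            fp_f = neg - tn_f
            deviation = np.zeros(tp_f.shape, dtype=float)
            ok = np.ones(tp_f.shape, dtype=bool)
            for name, value in reported.items():
                num, den = _METRIC_DEFS[name](tp_f, fp_f, fn_f, tn_f, n_i)
                computed = _metric_pct(
                    np.asarray(num, dtype=float), np.asarray(den, dtype=float)
                )
                diff = computed - value
                ok &= np.abs(diff) <= tol + 1e-12
                ok &= ~np.isnan(computed)
                deviation += np.where(np.isnan(diff), np.inf, diff**2)
            for idx in np.flatnonzero(ok):
                if tp_f[idx] + fp_f[idx] + fn_f[idx] + tn_f[idx] == 0:
                    continue
                matches.append(
                    ReconstructionCandidate(
                        ConfusionMatrix(int(tp_f[idx]), int(fp_f[idx]),
                                        int(fn_f[idx]), int(tn_f[idx])),
                        float(deviation[idx]),
                    )
                )
            # track the nearest miss for the closest-miss report
            finite = np.isfinite(deviation)
            if finite.any():
                j = int(np.argmin(np.where(finite, deviation, np.inf)))
                if (tp_f[j] + fp_f[j] + fn_f[j] + tn_f[j]) > 0 and (
                    closest is None or deviation[j] < closest.deviation
                ):
                    closest = ReconstructionCandidate(
                        ConfusionMatrix(int(tp_f[j]), int(fp_f[j]),
                                        int(fn_f[j]), int(tn_f[j])),
                        float(deviation[j]),
                    )

    matches.sort(key=lambda c: (c.deviation, c.matrix.as_tuple()))
    if matches and (closest is None or matches[0].deviation <= closest.deviation):
        closest = matches[0]
    return ReconstructionResult(
        candidates=matches, closest=closest,
        reported=dict(reported), tolerance=tol,
    )


# ---------------------------------------------------------------------------
# Cohort-level evaluation report
# ---------------------------------------------------------------------------


def evaluation_report(cohort, thresholds=None, targets: ScreeningTargets = None,
                      ref=None) -> dict:
    """Evaluate the ratio-only, dFLC-only and combined rules on a cohort.

    For each rule: the 2x2 matrix against uIFE truth, the full metric suite
    (both FN conventions side by side), Cohen's kappa and a verdict against
    the screening targets.  If no sample carries a uIFE result the report
    degrades to classification-only with an explicit notice.
    """
    from .markers import DEFAULT_REFERENCE
    from .ruleout import (RuleoutThresholds, VALIDATION_PRESET,
                          screen_positive_series)

    thresholds = thresholds or VALIDATION_PRESET
    targets = targets or ScreeningTargets()
    ref = ref or DEFAULT_REFERENCE

    truths = pd.Series(
        {r.sample_id: r.uife_result for r in cohort}, dtype=object
    )
    report: dict = {
        "cohort": cohort.name,
        "n": len(cohort),
        "thresholds": {
            "ratio_low": thresholds.ratio_low,
            "ratio_high": thresholds.ratio_high,
            "dflc_max": thresholds.dflc_max,
        },
        "targets": {"min_sensitivity": targets.min_sensitivity,
                    "max_fn": targets.max_fn},
        "rules": {},
    }
    have_truth = truths.notna().any()
    if not have_truth:
        report["notice"] = (
            "no uIFE results available: classification-only report, "
            "no diagnostic metrics"
        )

    for rule_name in ("ratio_only", "dflc_only", "combined"):
        screen = screen_positive_series(cohort, thresholds, rule=rule_name,
                                        ref=ref)
        section: dict = {
            "screen_positive": int(screen.sum()),
            "ruled_out": int((~screen).sum()),
            "avoided_fraction": float((~screen).mean()),
        }
        if have_truth:
            cm = confusion_matrix(screen, truths)
            metrics = compute_metrics(cm)
            section["matrix"] = {"tp": cm.tp, "fp": cm.fp,
                                 "fn": cm.fn, "tn": cm.tn}
            section["metrics"] = metrics.as_dict()
            section["targets_met"] = {
                "sensitivity": (metrics.sensitivity is not None
                                and metrics.sensitivity >= targets.min_sensitivity),
                "fn_rate_total": metrics.fn_rate_total < targets.max_fn,
            }
            section["targets_met"]["all"] = all(section["targets_met"].values())
        report["rules"][rule_name] = section
    return report


def report_markdown(report: dict) -> str:
    """Render an evaluation report as markdown."""
    lines = [f"# Screening evaluation: {report['cohort']} (n={report['n']})", ""]
    thr = report["thresholds"]
    lines.append(
        f"Rule-out thresholds: ratio in [{thr['ratio_low']}, "
        f"{thr['ratio_high']}], dFLC < {thr['dflc_max']} mg/L."
    )
    if "notice" in report:
        lines += ["", f"**Notice:** {report['notice']}"]
    for name, section in report["rules"].items():
        lines += ["", f"## Rule: {name}", ""]
        lines.append(
            f"- ruled out {section['ruled_out']} / "
            f"{section['ruled_out'] + section['screen_positive']} "
            f"(avoided fraction {100 * section['avoided_fraction']:.1f}%)"
        )
        if "metrics" in section:
            m = section["metrics"]
            cm = section["matrix"]
            lines.append(
                f"- 2x2 (tp, fp, fn, tn) = ({cm['tp']}, {cm['fp']}, "
                f"{cm['fn']}, {cm['tn']})"
            )
            def fmt(v):
                return "n/a" if v is None else f"{v:.2f}%"
            lines.append(
                f"- S {fmt(m['sensitivity'])}, E {fmt(m['specificity'])}, "
                f"PPV {fmt(m['ppv'])}, NPV {fmt(m['npv'])}"
            )
            lines.append(
                f"- FN of cohort {m['fn_rate_total']:.2f}%, "
                f"FN of positives {fmt(m['fnr_of_positives'])}"
            )
            if "kappa" in m:
                lines.append(
                    f"- Cohen's kappa {m['kappa']:.3f} "
                    f"(SE {m['kappa_se']:.3f}, 95% CI "
                    f"{m['kappa_ci_95'][0]:.3f}-{m['kappa_ci_95'][1]:.3f})"
                )
            verdict = "PASS" if section["targets_met"]["all"] else "FAIL"
            lines.append(f"- screening targets: {verdict}")
    return "\n".join(lines)


def cohort_realizing_matrix(cm: ConfusionMatrix, thresholds=None,
                            name: str = "reconstructed") -> "Cohort":
    """Build a synthetic cohort that reproduces a 2x2 table under a rule.

    Screen-positive samples get an extreme kappa clone profile (ratio far
    above the window, large dFLC); screen-negative samples sit at ratio 1
    with dFLC 0.  Truth (uIFE) follows the matrix cell.  Useful for turning
    a reconstructed published table back into per-sample data the classifier
    can be run on.
    """
    from .cohort import Cohort, SampleRecord, UIFE_KAPPA, UIFE_NEGATIVE
    from .ruleout import VALIDATION_PRESET

    thresholds = thresholds or VALIDATION_PRESET
    # values safely outside / inside the rule-out window
    hi_kappa = max(500.0, 100.0 * thresholds.ratio_high * 10.0)
    records = []
    cells = (
        ("tp", cm.tp, True, True), ("fp", cm.fp, True, False),
        ("fn", cm.fn, False, True), ("tn", cm.tn, False, False),
    )
    i = 0
    for cell, count, screen_pos, truth_pos in cells:
        for _ in range(count):
            i += 1
            kappa = hi_kappa if screen_pos else 10.0
            records.append(SampleRecord(
                sample_id=f"{cell}{i:05d}", patient_id=f"p{i:05d}",
                kappa_sflc=kappa, lambda_sflc=10.0,
                uife_result=UIFE_KAPPA if truth_pos else UIFE_NEGATIVE,
            ))
    return Cohort(records=records, name=name, source="synthetic")
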