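"""Serum free light chain markers: kappa/lambda ratio, dFLC, clonality.

The two quantities the rule-out screen consumes are the sFLC kappa/lambda
ratio and dFLC.  dFLC is defined here as ``|kappa - lambda|`` — the absolute
difference between the two chains — so it can be computed before knowing
which chain is clonally involved.  Clonality against a reference interval
uses strict inequalities: a ratio exactly on a bound is normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort import Cohort, SampleRecord
from .errors import UndefinedRatioError

KAPPA_CLONAL = "kappa_clonal"
LAMBDA_CLONAL = "lambda_clonal"
NORMAL = "normal"

CHAIN_KAPPA = "kappa"
CHAIN_LAMBDA = "lambda"
CHAIN_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ReferenceRange:
    """Diagnostic reference interval for the kappa/lambda ratio.

    Defaults to the conventional Freelite interval 0.26–1.65: a ratio above
    ``upper`` suggests a kappa clone, below ``lower`` a lambda clone.
    """

    lower: float = 0.26
    upper: float = 1.65

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"reference range requires 0 < lower < upper, "
                f"got ({self.lower}, {self.upper})"
            )


DEFAULT_REFERENCE = ReferenceRange()


@dataclass(frozen=True)
class MarkerPanel:
    """Derived per-sample serum markers."""

    ratio: float
    dflc: float
    involved_chain: str
    clonality_call: str
    indeterminate: bool = False


def classify_clonality(ratio: float, ref: ReferenceRange = DEFAULT_REFERENCE) -> str:
    """Classify a kappa/lambda ratio against a reference interval.

    Strictly above ``ref.upper`` is kappa-clonal, strictly below ``ref.lower``
    lambda-clonal, anything else (including the bounds themselves) normal.
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if ratio > ref.upper:
        return KAPPA_CLONAL
    if ratio < ref.lower:
        return LAMBDA_CLONAL
    return NORMAL


def compute_markers(
    record: SampleRecord, ref: ReferenceRange = DEFAULT_REFERENCE
) -> MarkerPanel:
    """Compute the marker panel for one sample.

    Raises
    ------
    UndefinedRatioError
        If ``lambda_sflc`` is zero: the ratio is not representable and the
        sample must be flagged rather than silently dropped.
    """
    if record.lambda_sflc == 0:
        raise UndefinedRatioError(
            f"sample {record.sample_id!r}: lambda_sflc is 0, "
            "kappa/lambda ratio undefined"
        )
    ratio = record.kappa_sflc / record.lambda_sflc
    dflc = abs(record.kappa_sflc - record.lambda_sflc)
    call = classify_clonality(ratio, ref) if ratio > 0 else LAMBDA_CLONAL
    if call == KAPPA_CLONAL:
        involved, indeterminate = CHAIN_KAPPA, False
    elif call == LAMBDA_CLONAL:
        involved, indeterminate = CHAIN_LAMBDA, False
    else:
        # in-range ratio: the larger chain wins but the call is indeterminate
        involved = (
            CHAIN_KAPPA if record.kappa_sflc > record.lambda_sflc
            else CHAIN_LAMBDA if record.lambda_sflc > record.kappa_sflc
            else CHAIN_INDETERMINATE
        )
        indeterminate = True
    return MarkerPanel(
        ratio=ratio, dflc=dflc, involved_chain=involved,
        clonality_call=call, indeterminate=indeterminate,
    )


def attach_markers(
    cohort: Cohort, ref: ReferenceRange = DEFAULT_REFERENCE
) -> pd.DataFrame:
    """Cohort table with marker columns appended.

    Samples with an undefined ratio get NaN ratio/dflc and a
    ``marker_error`` note instead of being dropped.
    """
    frame = cohort.to_frame()
    ratios: list[Optional[float]] = []
    dflcs: list[Optional[float]] = []
    calls: list[Optional[str]] = []
    errors: list[Optional[str]] = []
    for record in cohort:
        try:
            panel = compute_markers(record, ref)
        except UndefinedRatioError as exc:
            ratios.append(None)
            dflcs.append(None)
            calls.append(None)
            errors.append(str(exc))
        else:
            ratios.append(panel.ratio)
            dflcs.append(panel.dflc)
            calls.append(panel.clonality_call)
            errors.append(None)
    frame["ratio"] = ratios
    frame["dflc"] = dflcs
    frame["clonality_call"] = calls
    frame["marker_error"] = errors
    return frame
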