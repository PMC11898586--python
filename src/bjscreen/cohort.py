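"""Data model and CSV I/O for paired serum / 24-h urine cohorts.

A cohort is an ordered collection of :class:`SampleRecord` objects, one per
paired serum + urine observation.  Serum free light chains (sFLC) are in
mg/L, urine total protein in g/L and urinary M-protein in mg/24 h; units are
fixed and never auto-converted.  Urine immunofixation (uIFE) is the ground
truth and takes one of three levels: ``negative``, ``kappa_bjp`` or
``lambda_bjp`` — a sample is either free of Bence Jones protein (BJP) or
carries a single clonal light chain type.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import CohortParseError, CohortValidationError

UIFE_NEGATIVE = "negative"
UIFE_KAPPA = "kappa_bjp"
UIFE_LAMBDA = "lambda_bjp"
UIFE_LEVELS = (UIFE_NEGATIVE, UIFE_KAPPA, UIFE_LAMBDA)

#: Fixed CSV column order; optional fields are written as empty strings.
COLUMNS = [
    "sample_id",
    "patient_id",
    "kappa_sflc",
    "lambda_sflc",
    "urine_total_protein",
    "uife_result",
    "urine_mprotein",
    "egfr",
    "age",
    "sex",
]

_METADATA_PREFIX = "# bjscreen-cohort"


@dataclass(frozen=True)
class SampleRecord:
    """One paired serum/urine observation.

    Parameters
    ----------
    sample_id, patient_id
        Opaque identifiers; ``sample_id`` must be unique within a cohort.
    kappa_sflc, lambda_sflc
        Serum free kappa / lambda concentrations, mg/L.
    urine_total_protein
        24-h urine total protein, g/L (optional).
    uife_result
        Urine immunofixation outcome, the diagnostic ground truth (optional).
    urine_mprotein
        Urinary M-protein excretion, mg/24 h; only meaningful for
        uIFE-positive samples.
    egfr
        CKD-EPI estimated glomerular filtration rate, mL/min/1.73 m^2.
    """

    sample_id: str
    patient_id: str
    kappa_sflc: float
    lambda_sflc: float
    urine_total_protein: Optional[float] = None
    uife_result: Optional[str] = None
    urine_mprotein: Optional[float] = None
    egfr: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def validate(self) -> None:
        problems = []
        for name in ("kappa_sflc", "lambda_sflc", "urine_total_protein",
                     "urine_mprotein", "egfr", "age"):
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value):
                problems.append(f"{name} is not finite ({value!r})")
            elif value < 0:
                problems.append(f"{name} is negative ({value!r})")
        if self.uife_result is not None and self.uife_result not in UIFE_LEVELS:
            if "biclonal" in str(self.uife_result).lower():
                problems.append(
                    "biclonal uIFE results are not representable; uife_result "
                    f"must be one of {UIFE_LEVELS}"
                )
            else:
                problems.append(
                    f"uife_result {self.uife_result!r} not in {UIFE_LEVELS}"
                )
        if self.urine_mprotein is not None and self.uife_result not in (
            UIFE_KAPPA,
            UIFE_LAMBDA,
        ):
            problems.append(
                "urine_mprotein may only be present when uife_result is "
                "kappa_bjp or lambda_bjp"
            )
        if problems:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: " + "; ".join(problems)
            )


@dataclass
class Cohort:
    """Ordered collection of :class:`SampleRecord` with provenance."""

    records: list[SampleRecord]
    name: str = "cohort"
    source: str = "observed"  # observed | synthetic
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        for record in self.records:
            record.validate()
            if record.sample_id in seen:
                raise CohortValidationError(
                    f"duplicate sample_id {record.sample_id!r}"
                )
            seen.add(record.sample_id)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame with the fixed column order."""
        rows = [dataclasses.asdict(r) for r in self.records]
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return frame


def _parse_float(raw: str, column: str, row: int) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortParseError(
            f"row {row}: column {column!r}: cannot parse {raw!r} as a number"
        ) from exc


def read_cohort(path: str | Path, format: str = "csv") -> Cohort:
    """Read a cohort from CSV.

    The header row is mandatory and must name the :data:`COLUMNS` fields.
    An optional first line of the form ``# bjscreen-cohort name=... source=...
    seed=...`` carries provenance written by :func:`write_cohort`.  Row
    numbers in error messages count data rows starting at 1.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    name, source, seed = path.stem, "observed", None
    if text.startswith(_METADATA_PREFIX):
        meta_line, _, text = text.partition("\n")
        for token in meta_line[len(_METADATA_PREFIX):].split():
            key, _, value = token.partition("=")
            if key == "name":
                name = value
            elif key == "source":
                source = value
            elif key == "seed" and value not in ("", "None"):
                seed = int(value)
    try:
        frame = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise CohortParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("sample_id", "patient_id", "kappa_sflc", "lambda_sflc")
               if c not in frame.columns]
    if missing:
        raise CohortParseError(f"{path}: header missing columns {missing}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        kappa = _parse_float(row_map["kappa_sflc"], "kappa_sflc", i)
        lam = _parse_float(row_map["lambda_sflc"], "lambda_sflc", i)
        if kappa is None or lam is None:
            raise CohortParseError(
                f"row {i}: kappa_sflc and lambda_sflc are required"
            )
        uife = row_map.get("uife_result", "").strip() or None
        record = SampleRecord(
            sample_id=row_map["sample_id"].strip(),
            patient_id=row_map["patient_id"].strip(),
            kappa_sflc=kappa,
            lambda_sflc=lam,
            urine_total_protein=_parse_float(
                row_map.get("urine_total_protein", ""), "urine_total_protein", i
            ),
            uife_result=uife,
            urine_mprotein=_parse_float(
                row_map.get("urine_mprotein", ""), "urine_mprotein", i
            ),
            egfr=_parse_float(row_map.get("egfr", ""), "egfr", i),
            age=_parse_float(row_map.get("age", ""), "age", i),
            sex=row_map.get("sex", "").strip() or None,
        )
        records.append(record)
    return Cohort(records=records, name=name, source=source, seed=seed)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV; :func:`read_cohort` inverts it field-for-field.

    Provenance (name, source, seed) is kept on a leading comment line so
    synthetic cohorts stay reproducible through the round trip.
    """
    cohort.validate()
    path = Path(path)
    lines = [
        f"{_METADATA_PREFIX} name={cohort.name} source={cohort.source} "
        f"seed={cohort.seed}",
        ",".join(COLUMNS),
    ]
    for r in cohort.records:
        cells = []
        for col in COLUMNS:
            value = getattr(r, col)
            if value is None:
                cells.append("")
            elif isinstance(value, float):
                cells.append(repr(value))
            else:
                cells.append(str(value))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _mean_range(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_cohort(cohort: Cohort, ratio_reference=None) -> dict:
    """Cohort summary: demographics, uIFE positivity, clonality, ratio groups.

    ``ratio_reference`` is the kappa/lambda reference interval used to count
    elevated / reduced ratio samples (defaults to the conventional 0.26–1.65).
    Sections with no underlying data are reported as absent (``None``).
    """
    from .markers import ReferenceRange  # local import to avoid a cycle

    if len(cohort) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    ref = ratio_reference or ReferenceRange()
    n = len(cohort)
    summary: dict = {"name": cohort.name, "source": cohort.source, "n": n}

    sexes = [r.sex for r in cohort if r.sex is not None]
    summary["male"] = None
    if sexes:
        male = sum(1 for s in sexes if s.upper().startswith("M"))
        summary["male"] = {"count": male, "pct": 100.0 * male / len(sexes)}

    ages = [r.age for r in cohort if r.age is not None]
    summary["age"] = _mean_range(ages) if ages else None

    egfrs = [r.egfr for r in cohort if r.egfr is not None]
    summary["egfr"] = _mean_range(egfrs) if egfrs else None

    uprot = [r.urine_total_protein for r in cohort
             if r.urine_total_protein is not None]
    summary["urine_total_protein"] = _mean_range(uprot) if uprot else None

    truths = [r.uife_result for r in cohort if r.uife_result is not None]
    if truths:
        pos = sum(1 for t in truths if t != UIFE_NEGATIVE)
        kappa_n = sum(1 for t in truths if t == UIFE_KAPPA)
        lambda_n = sum(1 for t in truths if t == UIFE_LAMBDA)
        summary["uife"] = {
            "n_with_result": len(truths),
            "positive": {"count": pos, "pct": 100.0 * pos / len(truths)},
            "clonality_kappa": {"count": kappa_n,
                                "pct": 100.0 * kappa_n / len(truths)},
            "clonality_lambda": {"count": lambda_n,
                                 "pct": 100.0 * lambda_n / len(truths)},
        }
        for label, level in (("kappa", UIFE_KAPPA), ("lambda", UIFE_LAMBDA)):
            vals = [r.urine_mprotein for r in cohort
                    if r.uife_result == level and r.urine_mprotein is not None]
            summary["uife"][f"urine_mprotein_{label}"] = (
                _mean_range(vals) if vals else None
            )
    else:
        summary["uife"] = None

    ratios = []
    for r in cohort:
        if r.lambda_sflc > 0:
            ratios.append(r.kappa_sflc / r.lambda_sflc)
    if ratios:
        elevated = [x for x in ratios if x > ref.upper]
        reduced = [x for x in ratios if x < ref.lower]
        summary["ratio"] = {
            "reference": {"lower": ref.lower, "upper": ref.upper},
            "altered": {
                "count": len(elevated) + len(reduced),
                "pct": 100.0 * (len(elevated) + len(reduced)) / len(ratios),
            },
            "elevated": (
                {"count": len(elevated),
                 "pct": 100.0 * len(elevated) / len(ratios),
                 **_mean_range(elevated)} if elevated else None
            ),
            "reduced": (
                {"count": len(reduced),
                 "pct": 100.0 * len(reduced) / len(ratios),
                 **_mean_range(reduced)} if reduced else None
            ),
        }
    else:
        summary["ratio"] = None
    return summary


def summary_markdown(summary: dict) -> str:
    """Render :func:`summarize_cohort` output as a markdown table."""
    rows = [("n", str(summary["n"]))]
    if summary.get("male"):
        m = summary["male"]
        rows.append(("Male", f"{m['count']} ({m['pct']:.1f}%)"))
    for key, label in (("age", "Age (years)"), ("egfr", "eGFR"),
                       ("urine_total_protein", "Urine total protein (g/L)")):
        if summary.get(key):
            s = summary[key]
            rows.append((label, f"{s['mean']:.1f} ({s['min']:.3g}-{s['max']:.3g})"))
    uife = summary.get("uife")
    if uife:
        p = uife["positive"]
        rows.append(("uIFE positive", f"{p['count']} ({p['pct']:.1f}%)"))
        for label in ("kappa", "lambda"):
            c = uife[f"clonality_{label}"]
            rows.append((f"Clonality {label}", f"{c['count']} ({c['pct']:.1f}%)"))
    else:
        rows.append(("uIFE", "no results available"))
    ratio = summary.get("ratio")
    if ratio:
        rows.append(("Altered ratio",
                     f"{ratio['altered']['count']} ({ratio['altered']['pct']:.1f}%)"))
        for label in ("elevated", "reduced"):
            group = ratio.get(label)
            if group:
                rows.append((
                    f"{label.capitalize()} ratio",
                    f"{group['count']} ({group['pct']:.1f}%), "
                    f"mean {group['mean']:.3g} "
                    f"({group['min']:.3g}-{group['max']:.3g})",
                ))
    width = max(len(r[0]) for r in rows)
    lines = [f"| {'Field'.ljust(width)} | Value |",
             f"| {'-' * width} | ----- |"]
    lines += [f"| {k.ljust(width)} | {v} |" for k, v in rows]
    return "\n".join(lines)
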