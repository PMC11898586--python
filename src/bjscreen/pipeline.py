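"""End-to-end orchestration: full runs and the reconstruction suite.

:func:`run_full_pipeline` wires simulate/read -> markers -> (optional)
cutoff derivation -> classify -> evaluate, writing every artifact plus a
manifest with checksums so two runs of the same config are byte-comparable.
:func:`run_reconstruction_suite` inverts the published per-rule summary
statistics back to integer 2x2 tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .cohort import Cohort, read_cohort, summarize_cohort, write_cohort
from .cutoffs import (cutoff_to_dict, derive_dflc_cutoff, derive_ratio_cutoffs,
                      derive_uprotein_cutoff)
from .errors import BjscreenError, ConfigError, RocUndefinedError
from .evaluation import (ScreeningTargets, evaluation_report,
                         reconstruct_confusion_matrix, report_markdown)
from .markers import DEFAULT_REFERENCE, attach_markers
from .published import (DERIVATION_N_MAX, DERIVATION_TABLE, VALIDATION_N,
                        VALIDATION_STATS)
from .ruleout import RuleoutThresholds, classify_cohort, thresholds_preset
from .simulate import generate_cohort, preset_params

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``input_path`` (an existing cohort CSV) and
    ``simulator_preset`` must be supplied.
    """

    output_dir: Path
    input_path: Optional[Path] = None
    simulator_preset: Optional[str] = None
    thresholds: RuleoutThresholds = field(
        default_factory=lambda: thresholds_preset("validation")
    )
    control_policy: str = "uife_negative_only"
    targets: ScreeningTargets = field(default_factory=ScreeningTargets)
    derive: bool = True
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulator_preset is None):
            raise ConfigError(
                "exactly one of input_path and simulator_preset is required"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute the whole workflow; returns the output directory.

    Any stage failure is re-raised with the stage name prefixed so callers
    (and the CLI exit status) can report where the run died.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except BjscreenError:
                raise
            except Exception as exc:
                raise BjscreenError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- input ---
    if config.simulator_preset is not None:
        params = preset_params(config.simulator_preset, seed=config.seed)
        cohort = stage("simulate")(lambda: generate_cohort(params))
    else:
        cohort = stage("read")(lambda: read_cohort(config.input_path))
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path)
    written.append(cohort_path)

    # --- markers ---
    markers_path = out / "markers.csv"
    stage("markers")(
        lambda: attach_markers(cohort).to_csv(markers_path, index=False)
    )
    written.append(markers_path)

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(summarize_cohort(cohort), indent=2), encoding="utf-8"
    )
    written.append(summary_path)

    # --- cutoff derivation (optional; needs truth labels) ---
    if config.derive:
        def derive():
            result = {}
            sided = derive_ratio_cutoffs(cohort, config.control_policy)
            result["ratio"] = {
                "lambda_side": cutoff_to_dict(sided.lambda_side)
                if sided.lambda_side else None,
                "kappa_side": cutoff_to_dict(sided.kappa_side)
                if sided.kappa_side else None,
                "notes": sided.notes,
            }
            try:
                result["dflc"] = cutoff_to_dict(derive_dflc_cutoff(cohort))
            except RocUndefinedError as exc:
                result["dflc"] = {"absent": str(exc)}
            try:
                result["urine_total_protein"] = cutoff_to_dict(
                    derive_uprotein_cutoff(cohort)
                )
            except RocUndefinedError as exc:
                result["urine_total_protein"] = {"absent": str(exc)}
            return result
        cutoffs = stage("derive")(derive)
        cutoffs_path = out / "cutoffs.json"
        cutoffs_path.write_text(json.dumps(cutoffs, indent=2),
                                encoding="utf-8")
        written.append(cutoffs_path)

    # --- classification ---
    decisions = stage("classify")(
        lambda: classify_cohort(cohort, config.thresholds)
    )
    decisions_path = out / "decisions.csv"
    decisions.decisions.to_csv(decisions_path, index=False)
    written.append(decisions_path)

    # --- evaluation ---
    report = stage("evaluate")(
        lambda: evaluation_report(cohort, config.thresholds, config.targets)
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2), encoding="utf-8")
    written.append(report_path)
    report_md_path = out / "report.md"
    report_md_path.write_text(report_markdown(report), encoding="utf-8")
    written.append(report_md_path)

    # --- manifest ---
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "input": str(config.input_path) if config.input_path
        else f"preset:{config.simulator_preset}",
        "thresholds": dataclasses.asdict(config.thresholds),
        "control_policy": config.control_policy,
        "avoided_fraction": decisions.avoided_fraction,
        "files": {p.name: _sha256(p) for p in written},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return out


def run_reconstruction_suite() -> dict:
    """Invert the published per-rule summaries to integer 2x2 tables.

    Returns one section per published metric set with the candidate
    matrices (ranked, deterministic), whether the match is unique, and the
    closest miss for the sets that are not internally consistent as a
    single 2x2 (notably the urine-protein screen).
    """
    suite: dict = {"derivation": {}, "validation": {}}
    for name, spec in DERIVATION_TABLE.items():
        result = reconstruct_confusion_matrix(
            spec["metrics"], n_max=DERIVATION_N_MAX, decimals=2
        )
        suite["derivation"][name] = _describe(result, spec.get("consistent"))
    for name, metrics in VALIDATION_STATS.items():
        result = reconstruct_confusion_matrix(
            metrics, n=VALIDATION_N, decimals=1
        )
        suite["validation"][name] = _describe(result, True)
    return suite


def _describe(result, expected_consistent) -> dict:
    out = {
        "reported": result.reported,
        "n_candidates": len(result.candidates),
        "unique": result.unique,
        "candidates": [
            {"tp": c.matrix.tp, "fp": c.matrix.fp, "fn": c.matrix.fn,
             "tn": c.matrix.tn, "n": c.matrix.n, "deviation": c.deviation}
            for c in result.candidates[:5]
        ],
    }
    if not result.candidates:
        out["inconsistent"] = True
        if result.closest is not None:
            m = result.closest.matrix
            out["closest_miss"] = {
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn, "n": m.n,
                "deviation": result.closest.deviation,
            }
    return out
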