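# bjscreen

Serum free light chain (sFLC) rule-out screening for urinary Bence Jones
protein (BJP).

## The problem

Monoclonal free light chains appear in the urine (as BJP) of many patients
with plasma cell disorders — multiple myeloma, MGUS, Waldenström's
macroglobulinemia, AL amyloidosis.  The reference method for detecting and
typing BJP is immunofixation of a 24-h urine collection (uIFE), which is
slow, partly subjective, and burdensome for patients.  Serum free light
chains, by contrast, are measured automatically in minutes at every visit.

Physiologically, free light chains only spill into urine once serum
concentrations exceed the proximal tubular reabsorption capacity (roughly
133 mg/L for κ and 278 mg/L for λ at normal renal function).  A patient
whose serum κ/λ ratio is near normal and whose chains are nearly balanced
is therefore very unlikely to have BJP — which makes sFLC a natural
*rule-out* screen: order the 24-h urine study only when serum cannot
exclude BJP.

`bjscreen` implements that screen as a tested pipeline for laboratory
scientists and biostatisticians:

* **markers** — κ/λ ratio and dFLC = |κ − λ| per sample, clonality against
  a reference interval (default 0.26–1.65);
* **cutoff derivation** — two-sided ROC analysis (one curve per clone
  type), trapezoidal AUC, Youden-J optimal cutoffs with midpoint
  thresholds;
* **rule-out classifier** — a sample is ruled out iff its ratio lies in
  [0.8, 2] **and** dFLC < 12 mg/L (the validated preset; the exact derived
  thresholds 0.82 / 1.99 / 11.93 ship as an alternative).  Samples whose
  ratio cannot be computed are never ruled out;
* **diagnostic evaluation** — 2×2 tables against uIFE truth, the full
  metric suite with *both* false-negative conventions (fn/n and
  fn/(tp+fn)), Cohen's κ with SE and CI, screening-target verdicts, and an
  exhaustive integer search that reconstructs 2×2 tables from published
  percentages;
* **synthetic cohorts** — a seeded generator with the renal-threshold
  physiology above, so the whole pipeline runs without access to patient
  data.

## Worked example

```python
from bjscreen import preset_params, generate_cohort, evaluation_report
from bjscreen.evaluation import report_markdown

cohort = generate_cohort(preset_params("validation_like", seed=1))
print(report_markdown(evaluation_report(cohort)))
```

prints (abridged):

```
# Screening evaluation: synthetic-n716 (n=716)

Rule-out thresholds: ratio in [0.8, 2.0], dFLC < 12.0 mg/L.

## Rule: combined

- ruled out 462 / 716 (avoided fraction 64.5%)
- 2x2 (tp, fp, fn, tn) = (192, 62, 0, 462)
- S 100.00%, E 88.17%, PPV 75.59%, NPV 100.00%
- FN of cohort 0.00%, FN of positives 0.00%
- Cohen's kappa 0.800 (SE 0.024, 95% CI 0.752-0.847)
- screening targets: PASS
```

Read: of 716 synthetic samples, 462 (64.5%) would need no 24-h urine
study; every sample with urinary BJP was flagged for urine testing
(sensitivity 100% — synthetic clones are near-always heavy secretors, so
this is optimistic relative to real cohorts; see `docs/methods.md`).

The same workflow from the shell:

```bash
bjscreen simulate --preset validation_like --seed 1 --out cohort.csv
bjscreen classify --in cohort.csv --preset validation \
    --out decisions.csv --summary summary.json
bjscreen evaluate --in cohort.csv --out report.json
bjscreen run-all --sim-preset validation_like --seed 1 --outdir results/
```

Reconstructing published 2×2 tables from their printed percentages:

```python
from bjscreen import reconstruct_confusion_matrix

result = reconstruct_confusion_matrix(
    {"sensitivity": 90.20, "specificity": 87.74, "ppv": 70.76,
     "fp_rate_total": 9.22, "fn_rate_total": 2.42},
    n_max=300, decimals=2)
print(result.best.as_tuple())   # (46, 19, 5, 136) — unique
```

## Layout

```
src/bjscreen/
  cohort.py      data model, CSV I/O, cohort summaries
  markers.py     ratio, dFLC, clonality
  cutoffs.py     ROC, AUC, Youden cutoffs, per-marker derivations
  ruleout.py     the decision rule, presets, avoided-test accounting
  evaluation.py  2x2 metrics, Cohen's kappa, integer reconstruction
  simulate.py    seeded synthetic cohort generator
  published.py   published summary statistics used as reconstruction targets
  pipeline.py    full-run orchestration with manifest
  cli.py         `bjscreen` command-line interface
```

See `docs/methods.md` for the generative model, numerical conventions and
known limitations.
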