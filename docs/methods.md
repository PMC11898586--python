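# Methods

## The screen and its orientation

The screen answers one question per sample: can urinary Bence Jones
protein (BJP) be excluded from serum alone?  A sample is **ruled out**
when its serum free light chain (sFLC) κ/λ ratio lies inside the rule-out
window *and* dFLC is below its bound; otherwise urine testing is
indicated.  One orientation is fixed everywhere in the package: *screen
positive = urine testing indicated*, *truth positive = uIFE found BJP*.  A
false negative is a BJP-positive sample the screen ruled out — the error a
rule-out screen must keep rare.  The screening targets default to
sensitivity ≥ 85% with false negatives < 5% of samples screened.

dFLC is defined as |κ − λ|, the absolute difference, not the signed
involved-minus-uninvolved difference.  The absolute form needs no prior
knowledge of which chain is clonal, which is exactly the situation a
screen is used in; for in-range ratios the "involved" chain is reported as
the larger one but tagged indeterminate, and nothing downstream consumes
it.

Two false-negative conventions circulate in the screening literature —
fn/n (share of all samples) and fn/(tp+fn) (share of true BJP carriers,
the complement of sensitivity) — and published tables switch between them
without notice.  Both are first-class fields and always co-reported; the
target check uses fn/n and prints both.

## Thresholds and boundary conventions

Two presets ship:

| preset       | ratio window | dFLC bound | provenance                      |
|--------------|--------------|------------|---------------------------------|
| `validation` | [0.8, 2.0]   | < 12 mg/L  | the deployed, externally validated rule (default) |
| `derivation` | [0.82, 1.99] | < 11.93    | exact ROC-derived cutoffs       |

The ratio window is inclusive and the dFLC comparison strict, reading
"ratio 0.8–2 and dFLC < 12" literally; both are flags
(`ratio_bounds_inclusive`, `dflc_bound_strict`) because a site may prefer
the conservative reading.  Clonality against the reference interval
(default 0.26–1.65) uses strict inequalities: a ratio exactly on a bound
is normal.

## ROC and cutoff selection

The ratio is a two-sided marker, so cutoffs come from two one-sided ROC
analyses: λ detection with *lower is positive* (cases = uIFE λ-BJP),
κ detection with *higher is positive* (cases = uIFE κ-BJP).  Controls
default to uIFE-negative samples only: a κ-clone sample is not a
meaningful negative for the λ question.  The `all_non_case` policy adds
opposite-clone samples to the controls for sites that prefer the
all-comers reading; the choice is exposed because neither convention is
universal.

ROC enumeration and the trapezoidal AUC go through scikit-learn
(`roc_curve`, `auc`); ties are grouped, so the trapezoid equals the
Mann–Whitney concordance probability with half-credit for ties — the test
suite checks that identity against an independent pair-counting oracle on
1,000 random instances.

The operating point maximizes Youden's J = sensitivity + specificity − 1.
Candidate thresholds sit at midpoints between adjacent distinct observed
values (plus endpoints beyond the extremes), so a reported cutoff never
coincides with a datum and the > / ≥ distinction is moot.  Ties in J break
toward higher specificity (fewer urine tests for equal case capture), then
toward the more extreme threshold.  A marker with all values tied yields
J = 0 with an explicit degenerate flag and warning.

## 2×2 evaluation and Cohen's κ

All metrics are recomputed from integer counts; undefined metrics (empty
denominator) are reported absent with a reason rather than as NaN.
Cohen's κ uses p_o = (tp+tn)/n and p_e from marginal products, with the
classical large-sample standard error √(p_o(1−p_o)/n)/(1−p_e) and a
±1.96·SE interval.  Published κ standard errors computed by other software
may use a different variance estimator; κ itself is comparable, the SE
only approximately.

NPV and PPV are always the cohort's own — no Bayes adjustment to an
external prevalence — matching how direct 2×2 tables are reported.

## Integer reconstruction of published tables

Per-sample data behind published screening tables are rarely deposited.
`reconstruct_confusion_matrix` inverts a set of printed percentages back
to the integer 2×2 tables that could have produced them: an exhaustive
search over (tp, fp, fn, tn), pruned by the sensitivity-type constraints,
over a fixed n or all n up to a bound (≤ 2000).  A candidate matches when
every reported metric agrees within one unit in the last printed decimal
(10^−decimals): a full ulp rather than a half, because published tables
demonstrably mix rounding and truncation (e.g. 5/206 = 2.427% printed as
2.42).  Candidates are ranked by total squared deviation, then
lexicographically — the ordering is deterministic.  When no table fits,
the closest miss is reported instead of forcing a fit; two of the shipped
published columns (the urine-protein screen and the κ-side 1.99 column)
are in fact not internally consistent as a single 2×2 and are flagged as
such rather than "fixed".

The shipped validation-cohort summaries reconstruct cleanly at n = 716 and
agree on 198 BJP-positive samples across rules; the combined rule is
anchored by its printed rule-out counts (289 of 301 ruled-out samples
uIFE-negative), which together with the 198 positives fixes the full
table.  The acceptance script then *runs the classifier* on a cohort
realizing that table and measures sensitivity, NPV and the avoided
fraction from the classifier's own output, rather than quoting the
matrix back.

## The synthetic cohort generator

The generator emulates the physiology the screen exploits, per sample:

1. latent clone class: κ clone with probability 0.31, λ clone 0.205,
   otherwise no clone (the derivation-like mixture; the validation-like
   preset scales the clone fractions to 0.166/0.110 for a routine mixed
   population of ~27.5% positivity at n = 716);
2. polyclonal background per chain: log-normal, medians 12.5 (κ) and 12.0
   (λ) mg/L, chain-specific log-sd 0.15 plus a shared per-sample log-sd
   0.3 — the shared factor moves both chains together (as renal function
   does), keeping the healthy ratio tight around ~1.04 while absolute
   levels vary several-fold;
3. monoclonal production added to the involved chain: heavy-tailed
   log-normal, median 2000 mg/L (κ) / 3200 mg/L (λ), log-sd 0.9 — active
   secretory disease far above the renal thresholds, consistent with
   urinary M-protein excretions in the grams-per-day range;
4. eGFR from a truncated normal (mean 84, sd 24, clipped to [15, 113]
   mL/min/1.73 m²); the tubular reabsorption capacities (133 mg/L κ,
   278 mg/L λ) scale linearly with eGFR/90 when `egfr_scaling` is on,
   floored at zero;
5. urinary appearance: BJP present with probability
   logistic((involved − capacity)/width), width 25 mg/L.  The soft
   threshold models inter-patient variability in renal handling — some
   patients clear high sFLC loads without detectable BJP; width 0 gives
   the hard step, which the boundary-recovery tests use;
6. uIFE truth is positive exactly when BJP appears; positives draw a 24-h
   urinary M-protein (log-normal, medians 3340 / 4460 mg/24 h, log-sd
   1.2) which also feeds urine total protein (baseline log-normal median
   0.08 g/L, log-sd 0.8, plus the M-protein mass diluted into 1.5 L/day);
7. multiplicative log-normal assay noise, CV 5%, on κ, λ and urine
   protein.

All draws come from one `numpy` generator seeded by the single `seed`
field, in a fixed layout independent of parameter values: runs differing
only in a physiological parameter share their random numbers, which is
what makes the monotonicity properties (raising capacity never adds
positives; raising production never removes them) exactly testable.

Under the derivation-like defaults at n = 10,000 the generator lands at
~51.2–51.9% uIFE-positive across seeds (target 51.5%), clonality shares
near 31%/20.5%, an elevated-ratio group mean of ~250 (same order as the
~147 reported for comparable cohorts), and a combined-rule avoided
fraction of ~42–43%.

**What the generator does not emulate.**  Monoclonal production is drawn
from one unimodal heavy-tailed distribution: there is no treated/remission
subpopulation secreting *near* the renal threshold, no oligosecretory or
non-secretory class, no AL-amyloidosis pathway, no antigen-excess or
polymerization artifacts, and no longitudinal structure (each sample is an
independent visit; sample ≠ patient distinctions are ignored).  As a
result the synthetic markers separate cases from controls almost
perfectly — synthetic sensitivity and NPV approach 100%, noticeably above
the published 93.9%/96%.  Passing simulation tests therefore demonstrates
the *pipeline's* correctness (calibration, monotonicity, boundary
recovery, reproducibility), not the clinical operating characteristics;
those are checked through the reconstruction of the published tables.

## Numerical and degenerate-input conventions

* λ = 0 makes the ratio unrepresentable: the record raises
  (`UndefinedRatioError`) at the marker level and is classified
  URINE_TEST_INDICATED with reason "ratio undefined" at the cohort level —
  never silently dropped, never ruled out.
* Units are fixed (mg/L sFLC, g/L urine protein, mg/24 h urinary
  M-protein) and never auto-converted.
* Biclonal uIFE results are rejected at parse time: the three-level truth
  cannot represent them, and pretending otherwise would corrupt the 2×2.
* Missing optional markers exclude a record only from the analyses that
  need them, with a logged count.
* CSV floats are written with `repr`, so a synthetic cohort round-trips
  bit-for-bit and manifests of repeated runs have identical checksums.

## Problem sizes

The test suite uses n = 10,000 for calibration checks (binomial SE ≈ 0.5
points on a 50% fraction), n = 5,000 for cutoff-recovery (the recovered
boundary lands within the ±2 mg/L / ±0.1 ratio tolerances with margin),
and n ≤ 1,000 elsewhere; the reconstruction searches are exact and run in
well under a second each.  The full suite completes in a few seconds on
one CPU.
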