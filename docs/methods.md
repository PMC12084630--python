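# Methods

## Problem and data model

Every patient-hour between admission and discharge (or surgical
decompression) is an observation; hours are indexed from the time the
patient was last seen well (LSW), and admission must fall within 24 h of
LSW. The prediction target at hour *h* with horizon *W* ∈ {8, 24} is the
severity class of the maximum MLS over scans in the half-open window
(*h*, *h* + *W*]. A scan at the observation hour itself does not satisfy its
own window; hours with no scan inside the window are invalid and excluded.
This convention is what makes a 40-h inter-scan gap on the 24-h task
exclude exactly the first 16 post-scan hours and produce up to *W* valid
observations per scan. A 36-h target exists solely to train the
report-text classifiers and never feeds the downstream model.

Class edges are {0}, (0, 3], (3, 8], (8, ∞) mm: the source framing leaves
boundary membership open, and we assign exact boundary values to the lower
class (so "> 8 mm" is strict). The binary sensitivity-analysis target uses
the same convention at 5 mm.

## Feature engineering

- **Static (33)**: demographics, admission vitals/labs, NIHSS, history
  flags. Race and ethnicity are deliberately excluded from model inputs.
- **Dynamic EHR (16)** and **radiographic (36)** variables each yield two
  derived features per hour: the most recent value (`__last`,
  forward-fill) and the maximum over the previous 24 h (`__max24`, window
  (*h*−24, *h*]). Multiple raw values within one hour resolve as
  latest-wins for forward-fill and max for the rolling window.
- **Prior-MLS feature**: the MLS from the scan *before* the most recent
  one, forward-filled (73rd radiographic feature); missing until a second
  scan exists.
- **Text (12)**: per-scan report class probabilities for the three
  horizons, forward-filled between scans.

Observations begin only once a first scan exists (the current class must be
defined) and stop at the earliest of discharge, the hour before
hemicraniectomy, or admission + 168 h. The seven-day cap is anchored at
admission on the LSW axis — the hour axis is LSW-based while truncation is
described from presentation, so the cap is `admission_hour + 168`.

Missing values are mean-imputed with statistics fitted on the training
split only (never the test side, avoiding leakage; whether the original
analysis fitted per split or on the full cohort is not documented, and the
per-split choice is the conservative one). Mean imputation is extended
from statics to the derived dynamic/radiographic/text columns so the design
matrix stays rectangular; the extension is logged at fit time. A feature
with no observed training value raises an error naming the feature.

## Training

XGBoost (`hist`, single-threaded for bit-reproducibility) with a custom
softmax objective implementing the transition-weighted cross-entropy: per
observation weight *uᵢ* = 1 if the target class differs from the current
class ("filtered"), else *w* ∈ (0, 1]. Gradient *uᵢ(p − y)* and diagonal
curvature *uᵢ·max(2p(1−p), ε)* on the class margins — the library's
boosted-softmax convention, chosen so that *w* = 1 training coincides to
float precision with the builtin multiclass log-loss, and *w* < 1 with the
builtin objective under sample weights *uᵢ* (both equivalences are
asserted in the test suite as independent oracles). Observation weights
are also attached to the training matrix so the weighted quantile sketch
bins consistently with the loss. Probabilities are clipped at 1e-12 inside
logs; prediction ties break to the lowest class code.

Splits are five independent seeded 80/20 partitions **at the patient
level**; a disjointness check runs on every plan. (A bootstrap-resampling
toggle exists but defaults off.) Hyperparameters — including *w* — can be
tuned by seeded random search over a bounded space with inner-validation
*filtered* AUROC as the objective (falling back to overall AUROC, with a
warning, if the inner transition subset is degenerate). Defaults
(*w* = 0.5, 150 rounds, depth 4, η = 0.1, 0.9 sub/colsampling) are the
package's own neutral choices, not tuned values from any external study.

## Baseline

The comparator is a freshly trained ridge-regularized multinomial logistic
regression on the eight classic malignant-edema inputs: admission glucose,
admission HbA1c, previous stroke, thrombectomy at any point, thrombolysis
at any point (the "any point" flags are static by design, even before the
event hour), plus forward-filled current glucose, basal-cistern effacement
and MLS. Features are mean-imputed and standardized with training-split
statistics. It always shares the boosted model's exact splits and test
observations.

## Evaluation

AUROC/AUPRC: one-vs-rest TPR/FPR/precision/recall per class at every
threshold on a grid of 1001 equally spaced points in [0, 1] plus all
observed unique scores (making areas grid-insensitive), averaged across
classes with weights equal to true-class counts in the evaluated subset,
integrated by the trapezoid rule. An independent brute-force unique-cutoff
implementation agrees within 1e-6 in tests. Accuracy is argmax agreement.
Sensitivity/specificity use the worsening reformulation: truth = future
class exceeds current class; prediction = argmax class exceeds current
class. Metrics are computed on the overall set and on the filtered
(transition-only) subset; degenerate subsets yield explicit
undefined flags, never silent zeros. Split-level summaries are
mean ± t₀.₉₇₅,df=n−1·sd/√n (the CI construction was an open choice; the
t-interval is standard for five values).

## Synthetic cohort generator

The generator's defaults encode the study regime: admission uniform 2–20 h
post-LSW; gamma inter-scan intervals with mean 11.3 h (derivation profile)
or 18.8 h (validation profile); eventual-maximum-class mix
(0.15, 0.25, 0.35, 0.25), consistent with a cohort mean maximum shift
around 6–7 mm; MLS trajectories rising log-linearly from ≈0 at ictus to a
peak uniform in 48–120 h, decaying with a 60-h time constant, with 0.25-mm
Gaussian measurement noise; white-cell count, temperature and sodium ramp
up over the 24 h before each class transition with amplitudes (3 · 10³/µL,
1.2 °F, 2 mEq/L) scaled by `signal_strength` (default 1); other dynamic
variables are AR(1) around per-patient baselines. Treatments correlate
with severity (osmotic therapy near the first 3-mm crossing; decompressive
hemicraniectomy in ~35% of class-3 patients, censoring all later data).
Report probabilities are Dirichlet(1 + s·e_true) per horizon around the
true future window-max class with informativeness *s* (default 6);
missingness is MCAR per variable family (5% static, 10% dynamic, 8%
radiographic). All randomness flows from one seed through per-patient
`SeedSequence` substreams, so cohorts are byte-reproducible.

What the simulator does **not** emulate: real demographic distributions,
informative (non-random) missingness, inter-variable physiological
coupling beyond the planted drift, report free-text (fully synthetic runs
use drawn probabilities directly — the default test path), and the
measurement idiosyncrasies of real radiology workflows. Passing tests
therefore demonstrate that the pipeline recovers planted signal under its
own assumptions, not clinical performance; headline metrics reported on
real protected cohorts are out of reach by construction.

## Text stand-in

Reports are cropped to their Findings/Impression sections
(case-insensitive, order-independent; headerless text passes through with
a warning). The bundled classifier is token-count multinomial logistic
regression fitted per horizon on a patient-level 80/20 text split —
deterministic and desk-scale. Any adapter producing the same 12
per-scan probabilities can replace it; for a fine-tuned clinical
transformer the reference configuration is six epochs at an initial
learning rate of 2e-5 with categorical cross-entropy on the same targets.

## Feature importance

Exact tree-path-dependent TreeSHAP (via the booster's native contribution
predictor) gives per-observation, per-class, per-feature attributions on
the margin scale with local accuracy (bias + contributions = margin).
Reporting aggregates |attribution| by mean over observations and sum over
classes — one reasonable choice among several, as the aggregation statistic
was an open question — ranks features, and decomposes the top-20 importance
mass by category (report-text / radiographic / dynamic EHR / static),
stratified by current MLS class.

## Problem sizes and numerical choices

Test-suite runs use 20–300 simulated patients and 25–150 boosting rounds;
the transition-signal comparison runs 300 patients across five splits with
80 rounds. The random-predictor metric baselines use 50,000 balanced
observations. Tolerances: simplex checks 1e-9; curve-oracle agreement
1e-6; probability clipping 1e-12; hessian floor 1e-16. Degenerate inputs
(single-class targets, empty filtered sets, all-zero cohorts) raise or
flag explicitly as described above.

## Known limitations

- Synthetic-only validation; no claim transfers to real cohorts.
- The 33/16/36 variable name lists are plausible reconstructions with the
  correct cardinalities, not a published variable dictionary.
- Flat 4-class treatment; no ordinal-regression variant.
- MCAR missingness only; no learned imputation.
- The binary 5-mm mode reuses the 4-class training machinery with two
  active classes rather than a dedicated binary objective.
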