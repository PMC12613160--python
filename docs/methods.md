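# Methods

## The stress test and its difficulty grid

The test is a series of 16 treadmill walking trials. Each trial occupies a
cell of a motor × cognitive difficulty grid. The motor axis raises treadmill
speed relative to the subject's preferred walking speed and adds virtual
obstacles; the cognitive axis displays arithmetic expressions with more
digits for shorter times, answered as "sums to ≤ 4" or "> 4" on two buttons.
The default grid is 4×4. Three cells are fixed by the test definition: the
no-challenge cell (100 % speed, no obstacles, no arithmetic), the moderate
mid-grid cell (120 % speed, 2 digits / 5 s) and the hardest cell (140 %
speed, 3 digits / 3 s). The level-1 descriptors (100 % speed with obstacles;
1 digit / 8 s) are package defaults, and the whole grid is configurable —
the exact intermediate rungs are a free design choice, only the anchors are
pinned.

Trials 1–3 are a fixed lead-in (motor-focused, cognitive-focused, combined)
so every subject has the same learning experience; the remaining 13 trials
are the 12 remaining non-baseline cells plus one repeated cell in
seeded-random order. The baseline (0, 0) cell is scored from the plain
baseline walk rather than a dedicated trial; this reconciles 16 trials with
full coverage of the 15 challenge cells. Trial durations are drawn uniformly
from 0.45–2 min and do not influence scoring.

## Generative model of the synthetic cohort

No subject-level data are distributed with the analysis, so the package
ships a generator whose defaults define the study conditions: 68 healthy and
76 diagnosed subjects, ages truncated-normal on 18–85 with per-group means
(SD) of 51.1 (17.7) and 66.2 (10.6) years, and a 70/30 training split of
41 + 57 versus 27 + 19.

**Latent reserve.** Each subject carries an unobserved reserve capacity

    R = r0 − r_age·(age − 50) − r_group·1[diagnosed] + N(0, σ_R)

with defaults r0 = 4.5 load units, r_age = 0.015 per year, r_group = 1.35,
σ_R = 0.8. Reserve is expressed in units of task load, so R ≈ 4.5 means the
subject tolerates a combined load of about 4.5 difficulty steps before
tipping.

**Tipping point.** Latent performance in cell (m, c) with load
L = w_m·m + w_c·c (default unit weights) is

    P(m, c) = b − δ·L − λ·max(0, L − R)

a shallow common decline (δ = 0.25 per step) plus a collapse once load
exceeds reserve. The default λ = 13 makes the collapse nearly cliff-like:
within roughly half a difficulty step past the tipping point a subject falls
to their performance floor. This steepness is a deliberate choice — it
reproduces the threshold narrative (performance is maintained until
resources are exhausted, then fails), it gives the diagnosed group the
early-collapse convexity that makes the face-validity group coefficient
robustly positive, and it keeps healthy subjects intact at moderate load
while saturating both groups at the hardest cells (the U-shaped overlap
pattern).

**Feature links.** Observable trial features are monotone links of P with
measurement noise, all saturating at physiologic limits so that group
differences compress once everyone has collapsed:

* answer accuracy — the subject knows the answer with probability
  expit(a0 + a1·P) and otherwise guesses one of the two buttons, so
  accuracy floors at ½; per-expression Bernoulli draws over the expressions
  that fit in the trial (true labels from the sum-≤ 4 rule);
* reaction time — log-linear decreasing in P, smoothly saturating (tanh)
  toward the response window, the smaller of the display time and a 2.5 s
  timeout;
* obstacle success — binomial with logistic success probability and a small
  residual pass rate (0.08) even after collapse;
* gait features (mean and SD of step length, gyroscope amplitude at
  mid-swing, gait asymmetry) — linear in P with floors/ceilings on the
  systematic part (e.g. step length cannot shrink below 18 cm) and Gaussian
  measurement noise on top, so even floored subjects vary.

Each subject also receives random intercepts on every link (step length
±5.4 cm, log reaction time ±0.34, etc.) representing idiosyncrasy unrelated
to reserve; these widen the reference SDs to realistic between-subject
magnitudes. All stochastic components scale with a single `noise_scale`
(0 gives a fully deterministic cohort).

**Proxies and volumes.** Clinical proxies (education, MoCA, TMT A/B, Stroop,
preferred walking speed) and TIV-adjusted volume surrogates (whole-brain
GM/WM, bilateral caudate, putamen, hippocampus, pallidum, amygdala, inferior
frontal and superior medial frontal) are linear in R and age plus noise,
clipped to plausible ranges. Group mean levels follow the published cohort
summaries; proxy noise is set so each proxy's group-discrimination AUC
matches its published value (0.65–0.83) — matching both the printed
within-group SDs and the printed AUCs simultaneously is impossible under
normality, and the AUCs govern the comparative analyses, so they take
precedence. Sex is assigned 50/50 independent of everything. The latent
truth (R and P per cell) is written to a separate table and never appears in
observable files.

**Calibration.** The reserve, load, floor and heterogeneity defaults were
calibrated jointly, once, so that the full pipeline reproduces the published
cohort's MCR-index summaries — 20-cohort mean index 75.1 (healthy) and 43.2
(diagnosed) against printed means of 74.9 and 45.5 — while preserving the
qualitative validation patterns (declining planes, positive group effect,
U-shaped overlap, index dominance over single proxies, Spearman ≥ 0.7 with
the latent reserve). The diagnosed mean sits ~2 points below the printed
value: the real cohort's index minimum lies 3 SD below the diagnosed mean,
a left tail that a Gaussian reserve with floor-bounded collapse cannot quite
produce without destroying the overlap pattern.

## Scoring and the MCR index

Features are standardized against healthy-training reference statistics at
the easiest condition carrying the feature: gait features against the
baseline walk, cognitive features against cell (0, 1), obstacle success
against cell (1, 0). Standardizing per cell instead would flatten the
healthy plane and erase the difficulty gradient. Sample (n−1) SDs are used
(small reference groups); a zero-variance feature is a hard error. Each
z-score is oriented so higher is better (reaction time, step-length SD and
asymmetry are negated).

A cell's score is the equal-weight mean of its available oriented z-scores
(weights configurable); repeated cells are averaged at the score level.
Missing cells are a hard error by default — silent imputation would distort
the index — with optional nearest-neighbour (Manhattan) imputation behind a
flag.

The reference plane is the cell-wise median (midpoint convention for even
counts) of the healthy training planes. A subject's raw index is the
unweighted mean over the 16 cells of (plane − reference); the 0–100 index is
the affine map fixed by the minimum and maximum raw values in the full
training cohort (both groups — the published extremes span both), retained
for test subjects and clipped to [0, 100]. Whether the published index clips
or can exceed its range on new subjects is not stated; clipping is chosen
because the attained bounds are reported as exactly 0 and 100.

## Validation battery

* **Face validity.** OLS of the per-cell scores on motor ordinal, cognitive
  ordinal (linear 0–3 coding, since effects are interpreted per level), a
  healthy indicator and difficulty × group interactions; coefficient t tests
  use residual degrees of freedom. Repeated cells enter as independent
  observations (no random effects) — a documented simplification.
* **Known-groups validity.** Per-cell overlap of the two groups' score
  densities: Gaussian KDE with Silverman bandwidth per sample, evaluated on
  a common 512-point grid spanning both samples ± 3 bandwidths; overlap is
  the trapezoidal integral of the pointwise minimum, clipped to [0, 1]. The
  index's discrimination is summarized by the Mann–Whitney AUC (ties ½) with
  a DeLong 95 % CI on the held-out test set, and paired one-sided DeLong
  tests compare the index's AUC to each proxy's (same-subject covariance;
  identical classifiers give p = 0.5 by convention). AUC is computed
  directly on scores — the univariate logistic fit is retained only to
  report direction, since AUC is invariant to the monotone link.
* **Construct validity.** Spearman correlations (midranks, t-approximation
  p-values) of the index with each oriented proxy and each volume,
  BH-adjusted separately within the clinical and the imaging family; an
  optional age-adjusted panel rank-transforms all variables, residualizes on
  age ranks by least squares and correlates the residuals (t with n − 3 df).

## Numerical and reproducibility choices

One global seed feeds a `SeedSequence` hierarchy: one child per pipeline
stage, one per subject inside the generator, so stages and subjects are
independently reproducible and every artifact regenerates bit-identically
(checksummed in `manifest.json`). CSV artifacts carry a seed comment line;
model artifacts are JSON. Degenerate inputs (empty reference sets,
zero-variance features, single-class labels, constant vectors, min = max
scalers, rank-deficient designs) raise typed errors that the CLI maps to
exit codes 2 (schema), 3 (config) and 4 (computation).

Problem sizes: the test suite and the acceptance script run the full
pipeline on 20 default cohorts (144 subjects × 17 trial records each),
about 2–3 s per cohort; the whole suite completes in roughly two minutes.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: graded
performance decline, a reserve-dependent collapse, group separation that
peaks at moderate difficulty, proxy and volume correlations driven by a
shared latent, and realistic missingness (no cognitive features in
motor-only trials and vice versa). It does not emulate raw IMU waveforms,
VR obstacle geometry, learning or fatigue across trials, diagnosis subtypes
(a single pooled "diagnosed" class), disease duration, sex effects, or
non-Gaussian severity tails — so passing tests demonstrate correctness of
the pipeline under the modelled conditions, not clinical performance on
real recordings.

## Known limitations

* The published scoring framework behind the standardized performance scores
  is approximated by the easiest-condition standardization scheme described
  above; the original's exact per-level scheme is not public.
* Plane scores are monotone in difficulty within each feature regime; at
  full saturation, cells scored from different feature sets can differ
  slightly in floor depth, so monotonicity across the focused-row/combined
  boundary is not guaranteed.
* The linear face-validity model is fit to a response that is nonlinear by
  construction (hinge + floors); its group main effect is an extrapolated
  intercept contrast and should be read qualitatively.
* KDE overlap with Silverman bandwidths oversmooths sharply saturated
  distributions; overlap rates at heavily floored cells are estimates with
  appreciable seed-to-seed variability.
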