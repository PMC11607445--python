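# Methods

This note documents the models, rules, and numerical choices implemented in
`optab`, and what the synthetic testbed does and does not establish.

## Problem setting

Sepsis treatment requires choosing among antibiotics (here Vancomycin,
Ceftriaxone, Piperacillin/Tazobactam, singly or in pairs — six candidate
options) under uncertainty about the pathogen, with efficacy assessable only
~48 h after initiation and with drug-specific toxicity risks: Vancomycin is
nephrotoxic (creatinine, acute kidney injury), Ceftriaxone hepatotoxic
(bilirubin total, alanine transaminase).  The package implements an
online-updateable forecaster of disease progression (SOFA score plus the
three side-effect labs) under each candidate option, and an iterative
selection procedure that minimizes forecast SOFA subject to contraindication
rules.

## Clinical rule layer

* **SOFA.**  Six organ subscores on levels 0–4, summed (0–24).  The
  aggregate is the trailing-24 h worst value per subscore, evaluated on the
  half-open window (t−24 h, t]; an empty window carries the last known level
  forward and a subscore is 0 before its first observation (avoiding
  artificial score collapse under sparse sampling).  Breakpoint tables are
  configuration data (`SofaConfig`); the defaults are the standard Sepsis-3
  tables, with the cardiovascular subscore consuming a pre-derived
  vasopressor tier because dose conventions vary between sites.
* **Suspicion of infection (SOI).**  Antibiotic administration followed by a
  culture within 24 h, or culture followed by an antibiotic within 72 h,
  boundaries inclusive; the SOI time is the earlier event.
* **Sepsis-3 label.**  Septic iff some SOFA value ≥ 2 falls in
  [SOI − 48 h, SOI + 24 h]; onset is the earliest qualifying SOI time.
* **Stage-1 AKI.**  Creatinine rise ≥ 0.3 mg/dl within 48 h, or ≥ 1.5× the
  baseline creatinine over the previous 7 days (baseline = window minimum,
  the conservative, guideline-typical aggregator), or urine output
  < 0.5 ml/kg/h sustained over a contiguous span of ≥ 6 h (spans longer than
  12 h also trigger: the 6–12 h wording bounds the stage, not an exclusion).
* **Contraindication warnings.**  Vancomycin: creatinine > 2 mg/dl (observed
  or forecast) or Stage-1 AKI.  Ceftriaxone: ALT > 280 U/L or bilirubin
  total > 2.4 (male) / 2.2 (female) mg/dl.  Thresholds sit in
  `ContraindicationRuleSet` and are evaluated over both observed history and
  the forecast horizon, so anticipated toxicity can warn before a lab
  crossing is observed; flags restrict this to one side.

All window-boundary readings (inclusive SOI/label windows, half-open rolling
window) are recorded here because equally defensible alternatives exist; the
rule engines are tested against exhaustive brute-force scans, so the chosen
conventions are locked by the suite.

## Preprocessing

Variables measured in fewer than 50% of patients are dropped (exactly 50%
is kept).  Remaining variables are kept when the absolute Spearman
correlation with SOFA exceeds 0.3 in at least one 12 h interval; each
patient contributes its within-bin mean and pairs are pooled across patients
(the within-bin aggregation is not uniquely determined by the rule as
stated; a raw-observation mode is provided).  SOFA and the outcome labs are
always retained.  Timestamps are rounded to hours with a keep-latest
collision rule (keeping the later raw observation preserves online
causality; a mean mode exists).  Variables are z-normalized with statistics
fitted on the training split only and reapplied unchanged elsewhere —
pooling over all splits would leak test statistics into training.  Initial
values are completed by K-nearest-neighbour imputation (Euclidean distance
on commonly observed normalized entries, k = 5) against training-split
donors.  Each variable gains a cumulative observation-count channel
(missingness is informative); counts are scaled by 0.1 and the time channel
by 1/24 so all control channels move on comparable scales.

**Rectilinear control path.**  The hourly record becomes a knot sequence in
which, within each hour, the time channel first advances at held values and
the value channels then update at frozen time.  This ordering makes the path
on [t0, t] depend only on data observed by t: appending later data extends
the knot sequence without touching existing knots, which is what makes every
encoder output bit-stable under future appends (the reverse ordering breaks
this and is rejected by the causality property test).

## Forecasting model (TE-CDE)

Encoder: a neural controlled differential equation
x(t0) = g_eta(z_t0, a_t0, d), dx = F_theta(x) dX(s), driven by the
rectilinear path of time, covariates, masks, and treatment indicators.
Decoder: an uncontrolled neural ODE x' = f_phi(x) initialized from the
encoder's latent state at t + eps (eps = 1 h) through a residual map
x + g_phi(x, d); it embodies "treatment continues unchanged" over the
forecast horizon, which matches the clinical protocol of holding the chosen
antibiotics between efficacy evaluations.  Outcome heads map latent states
to the R = 4 outcome channels; the treatment head uses an element-wise
logistic link (one Bernoulli probability per antibiotic) because pairs
co-occur and the treatment loss is a per-channel binary cross-entropy; a
softmax link is available behind a flag.  All maps are two-hidden-layer
tanh perceptrons (hidden width 48, latent dimension P = 10 by default).

**Numerics.**  The rectilinear path has a piecewise-constant derivative, so
the driven CDE restricted to one knot segment is an autonomous smooth ODE;
each segment (and each decoder hour) is integrated with fixed-step classical
RK4, by default one step per segment.  Fixed stepping gives bit-exact
reproducibility and exact causality; the refinement test (1 vs 2 vs 4
subdivisions) shows changes far below the 1e-3 tolerance at the package's
scales, so further subdivision buys nothing.  Non-finite states raise an
integration error immediately.

**Decoder initialization.**  g_phi's correction and f_phi's field start at
zero, so the initial decoder is the persistence forecast (the anchor state
carried flat).  Autonomous tanh fields trained from random initializations
tend toward contractive dynamics whose trajectories collapse toward an
attractor, flattening the very treatment contrasts the selector needs; the
persistence start preserves anchor information along the whole horizon and
lets training bend trajectories away from it.

## Training

Losses: the outcome loss is the mean squared error over *observed* outcome
entries with time index ≥ t_start (unobserved labs cannot contribute
error); the treatment loss is the conventional non-negative binary
cross-entropy over the M treatment channels, probabilities clipped at 1e-7
with a warning.  The combined objective trades outcome fit against
confounding balancing with weight mu: the treatment term is maximized with
respect to the encoder (so the latent state stops predicting upcoming
treatment assignment, mitigating time-dependent confounding) while the
treatment head minimizes it.  Two mechanisms are provided — a
gradient-reversal node (default) and an explicit negated term with separate
adversary updates — and a test verifies they produce identical encoder
gradients.

Two stages: (1) encoder, outcome head and adversary on one-hour-ahead
targets with t_start = 1; (2) encoder frozen, decoder outcome head seeded
from the trained encoder head, decoder maps fit on outcomes over
(t+1, t+48] from anchor hours drawn per batch over the grid (the earliest
anchor is always included, since deployment decisions are taken at onset
where assimilation is minimal).  Adam (lr 1e-2, dropped 3× midway through
stage 2), batch 100, early stopping on validation outcome loss with the
best parameters restored.  Training is seeded and CPU-deterministic.

The balancing term defaults to stage 1 only: the decoder sees no future
treatments, so there is no future-assignment signal to balance there; a
flag enables it in stage 2.

**Measuring balancing.**  How much confounding information the penalty
removed is quantified by a logistic probe: fit on the training cohort's
frozen predictive latents (pooled over several grid hours — pooling gives a
far stabler AUC than a single time point) predicting whether a
two-antibiotic option is ongoing, evaluated on a held-out cohort.  The
removable signal is intrinsically modest on this testbed: away from
decision times the treatment *effect* inverts the cross-sectional
severity–treatment association (combinations go to sicker patients, who
then improve), so even unbalanced latents sit well below perfect
treatment-predictability and measured AUC drops vary with the cohort draw.

## Antibiotic selection

At decision time t the candidate set is every singleton and pair over the
antibiotics not known (from resulted cultures) to be resistant.  The
candidate option enters the encoder only through the treatment channels on
(t, t+eps]: the decision-time value knot's treatment channels are replaced
by the candidate (a decision switches treatment *at* t — keeping the
factual assignment there would leak the clinician's choice into every
branch), the path advances one hour, and the decoder extrapolates.  The
selected option is the forecast-SOFA argmin at t + horizon over
warning-free candidates (constrained mode; if every option is warned the
global argmin is recommended with warnings attached rather than refusing,
because untreated sepsis is lethal — a hard-refusal mode is a flag away) or
over all candidates (unconstrained).  Options within `equivalence_margin`
of the minimum count as tied and resolve toward fewer antibiotics, then
lexicographically (de-escalation preference); the margin defaults to 0
(strict argmin).

Decisions run at onset (48 h horizon) then every 24 h (24 h horizon);
arriving resistance results insert a mid-window decision; fungal/viral
culture results and a SOFA score that is non-increasing and strictly lower
over the trailing 48 h emit physician notifications without changing the
ranking.

## Synthetic testbed

Because the real cohorts behind this class of model are credentialed-access
and counterfactuals are unobservable in any real data, all quantitative
claims are evaluated on a simulator with a full counterfactual oracle.

Latent severity follows a mean-reverting diffusion
du = κ(u_eq − u)dt + δ dt + σ dW (Euler–Maruyama at 0.25 h; κ = 0.02/h,
σ = 0.15 severity-units/√h, u_eq four units above onset severity so
untreated disease worsens).  δ is the option's summed per-pathogen-class
efficacy; the default matrix follows textbook spectra (Vancomycin strong
against gram-positives, Ceftriaxone/Piperacillin-Tazobactam against
gram-negatives, Piperacillin/Tazobactam strongest for mixed infections;
fungal and viral classes get zero efficacy so the selector's notification
path is exercised).  Effect magnitudes were set so that an effective option
separates from its runner-up by roughly 1–3 SOFA points at 48 h, i.e. a
few times the stochastic 48 h noise sd — the scale at which effective
antibiotic therapy visibly changes organ-failure trajectories and at which
option recovery is statistically identifiable at a few hundred training
patients.  Twelve time-dependent variables are affine in severity with
per-patient baselines (one, glucose, is deliberately uncoupled to exercise
the correlation filter; platelets and red-cell distribution width
additionally carry pathogen-class offsets, the observable signature that
makes class-conditional treatment response learnable from baseline data).
Vancomycin adds +0.012 mg/dl/h to creatinine while ongoing; Ceftriaxone
+0.010 mg/dl/h to bilirubin and +1.2 U/L/h to ALT.  Observations arrive by
per-variable Poisson processes (SOFA ≈ hourly, labs every ~10–15 h), thinned
20%, with measurement noise; each variable is observed at onset with
probability 0.8 (SOFA always).

Treatment assignment is a softmax policy whose score rises with current
SOFA for two-antibiotic options, falls with creatinine for
Vancomycin-containing options, penalizes combinations at baseline, and
rewards keeping the incumbent option (clinical inertia).  This produces
time-dependent confounding (sicker patients get broader coverage),
realistic persistence, and non-empty single-antibiotic factual groups for
the side-effect contrast procedure.  Decision times are 0, 48, then every
24 h over a 96 h horizon.

All six option paths per patient and decision time reuse one Brownian draw,
so counterfactual contrasts are noise-free and the ground-truth best option
is exactly the drift ordering; ties (fungal/viral) resolve by the same
fewest-antibiotics-then-lexicographic rule the selector uses.

**What passing does not show.**  The simulator's labs are affine in a
one-dimensional severity; real organ systems decouple.  Class markers are
far cleaner than real hematology; pathogen class is effectively observable
at onset, which real cohorts only approximate after culture results.
Binary treatment channels ignore dosing entirely.  Recovery of the
simulator's effects therefore demonstrates that the pipeline is wired
correctly and can extract confounded treatment effects at realistic
sparsity — not that it would reach the same accuracy on hospital data.

## Evaluation procedures

* **Forecast-error grids**: per (observation time, horizon) cell, squared
  error of decoder forecasts against held-out observations divided by the
  variable's variance, so a predict-the-global-mean baseline scores 1; with
  the normalizer computed over the grid's contribution multiset that
  identity is exact and is asserted to 1e-6.  Sparse labs get a centered
  5-cell moving average along the observation-time axis.
* **Side-effect contrast**: patients factually treated with a single
  antibiotic are sampled equally per group without replacement; each
  sampled patient is simulated under Vancomycin and under Ceftriaxone from
  the factual treatment start for 72 h and the per-lab difference is
  tracked per time point (kernel density summaries by Gaussian KDE,
  reference bandwidth, visualization only).
* **Counterfactual/factual matching**: patients treated within 3 h of
  onset whose factual option differs from the selected optimum are matched
  (Euclidean distance on normalized onset covariates, ties by patient id)
  to the nearest patient factually given that optimum; the mean absolute
  SOFA difference between prediction and matched factual course is compared
  against the same-treatment factual-matching baseline; 95% CIs by normal
  approximation over pairs (bootstrap flag available).
* **Average treatment improvement**: per patient, forecast SOFA under the
  selected optimum minus under the factual option from the first treatment
  time over 48 h, averaged with 95% CIs and integrated by the trapezoid
  rule; in unconstrained mode the value at the horizon is ≤ 0 per patient
  by construction of the argmin.

## Problem sizes

The reproduction study uses a 500-patient cohort (400 train / 50 validation
/ 50 spare) plus an independent 100-patient evaluation cohort on a 96 h
horizon, latent dimension 10, hidden width 48, 40 encoder and 60 decoder
epochs — sizes at which the full pipeline (simulation, two-stage training,
selection, and evaluation) completes in minutes on one CPU core while the
acceptance properties remain measurable.

## Known limitations

The decoder under-recovers the magnitude of treatment contrasts relative to
the simulator's truth (shrinkage toward the conditional mean is typical of
regularized forecasters trained on confounded assignments); rankings are
correct far above chance but exact top-1-of-6 recovery remains the hardest
property at these sample sizes.  The urine-output AKI criterion interprets
"sustained" via contiguous sub-threshold observations and is sensitive to
sampling gaps.  The treatment head's logistic link treats antibiotics as
independent channels; the softmax alternative renormalizes across
antibiotics and changes the balancing geometry.
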