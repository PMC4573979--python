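# Methods

This note records the models, defaults and design choices behind
`seropanel`, and what the synthetic-data generator does and does not
emulate.

## Signal model of the array generator

Spot intensities are log-normal. For sample *i* and antigen *j* the true
log signal (in foreground/background ratio units) is

    log r_ij = μ_b + σ_b ε_ij + δ_j 1{i recognizes j},

with baseline median `exp(μ_b)` = 1.2 ratio units (1200 normalized MFI
after the ×1000 unit scale), σ_b = 0.45, and a recognition shift
δ_j = log 10 by default (recognized spots read ~12000 normalized MFI).
Replicate spots multiply by `exp(N(0, 0.08))` (≈8% spot CV, four
replicates); each array multiplies all of its spots — IgG dilution curve
included — by a log-normal drift factor `exp(N(0, 0.3))`. Because the
drift also moves the curve, within-array normalization is identifiable
and testable by recovery. An injected outlier sample's factor multiplies
its antigen and control spots but *not* the IgG curve: aberrant serum
reactivity does not touch the detection-antibody calibrant, so
normalization cannot absorb it and the PCA screen can see it.

Recognition events are Bernoulli at per-group probabilities; an optional
Gaussian-copula correlation (`recognition_rho`) couples them through a
per-sample latent reactivity factor, emulating co-recognized antigen
blocks. Negative-control spots are calibrated so that the post-
normalization mean + 2 SD sits at the 4000-normalized-MFI design target
(control log-SD 0.15). With baseline parameters as above, the implied
false-positive rate of the positivity call on background antigens is
≈0.4% per serum.

The measurement chain (raw fg/bg → LAD affine map onto the cross-array
median IgG curve → replicate CV% filter at 50% → mean of surviving
replicates → threshold call) is the analysis's own preprocessing; no
step is bypassed for synthetic data.

What the generator does **not** emulate: spatial artefacts within
slides, antigen-specific printing variability, cross-reactivity between
antigens, batch effects across hybridization days, or heavy-tailed
"sticky serum" polyreactivity on arrays. Passing tests therefore show
that the pipeline recovers designed structure under the stated noise
model, not that it is robust to every artefact of real scans.

## Preprocessing decisions

* The published rule "signal < 0 → impute group mean" cannot arise from
  a fg/bg ratio; it is applied to *invalid* spots (background ≤ 0,
  missing, or QC-failed cells), preserving the imputation intent for the
  failure modes a ratio can produce.
* Normalization is an affine monotone map fitted by exact least absolute
  deviations (the optimal LAD line interpolates two curve points, so the
  handful of IgG points is enumerated — deterministic, robust to a
  corrupted point, and slope-constrained positive). The reference curve
  is the cross-array median per dilution level, anchored to nominal
  amounts for the unit scale.
* Replicate summary is the arithmetic mean of surviving replicates;
  CV ceiling 50% by default (configurable).
* All positivity comparisons are strict (`>`); boundary ties are
  negative, consistently with the validation-phase rule.

## Ensemble and outlier screen

Majority subsets take females = round(ñ·3/4), males = ñ − females
(exact at the default ñ = 24 → 18 F + 6 M). ñ = 24 mirrors the study
design this package implements; it is configurable because nothing in
the method fixes it.

The outlier screen computes Hotelling T² over the first 2 PCA scores of
the centered, unit-variance matrix. `alpha` (default 0.01) is
interpreted **familywise**: the per-sample cutoff uses the 1 − α/n F
quantile. A per-sample α would flag ~1% of a homogeneous cohort every
run, which contradicts the screen's purpose of catching gross atypical
samples only; with the Bonferroni form a clean cohort stays flag-free in
≈99% of runs while a 10-SD-shifted sample is still flagged essentially
always.

## PLS-DA, VIP, R-SVM

* Y coding: single centered 0/1 column; X autoscaled (centered, unit
  variance). Autoscaling is the chemometrics default for heterogeneous
  MFI scales.
* VIP is the standard Wold form with SS_a = q_a²(t_aᵀt_a) on the
  (deflated) centered response; ΣVIP² = p holds to machine precision and
  is asserted at 1e−6 relative in tests.
* R-SVM scores surviving features by s_j = w_j(mean₊ⱼ − mean₋ⱼ) with a
  linear SVM at fixed C = 1, eliminating the lowest-scoring half per
  round; final rank is reverse elimination order, ties broken by feature
  id for determinism. When comparing stability, the R-SVM list size is
  matched per subset to the PLS-DA VIP>1 set size, since a top-k rule
  needs a k and the VIP rule supplies a natural one.

## Cross-validation, component choice, permutation

Folds are stratified (k = 10) — required because subsets have 15 vs 24
class sizes; an error is raised if the smaller class cannot populate all
folds. Q²Y = 1 − PRESS/SS with SS corrected for the global mean. The
chosen component count is the *smallest* A whose Q²Y is within
`q2_tolerance` (default 0.01) of the maximum: a strict argmax drifts to
the largest A on 0.001-sized gains of a flat Q²Y curve, while the
tolerance form expresses the intended "ties go to the simpler model"
rule at realistic noise levels and reproduces the expected 1–3 component
choices on separable data.

The permutation test reshuffles labels only, keeps X intact, recomputes
R²Y and Q²Y under the same CV scheme at fixed A, and reports add-one
p-values p = (1 + #{null ≥ obs})/(N + 1), which can never be exactly 0.
Under the null the procedure is exchangeable, so the test is exact; a
calibration suite (signal-free data, N = 99, 200 repetitions) checks the
5% level within 3 binomial SE.

## Stability and panel selection

Tanimoto similarity of two empty selections is defined as 1 (identical
selections); the average excludes the diagonal. Recognition frequencies
for the selection filter are computed once on the full post-exclusion
discovery cohort (the consensus table carries single HD%/AIH% columns),
not per subset. The relative-frequency criterion is strict: VIP > 1 in
49 of 50 subsets excludes an antigen. Report tables round percentages
half-up to whole percent; exact values are kept in machine outputs. The
alternative "delta ≥ 25 points between AIH% and HD%" frequency form can
be expressed through the thresholds configuration but the two-threshold
form (<25% HD, >50% AIH) is the primary rule.

Stability-direction experiments use correlated planted signals
(30 informative antigens of 300, AIH recognition 0.45–0.75, copula
ρ = 0.5, 15 subsets): correlated, individually-moderate signals are the
regime where a multivariate projection distributes importance across a
correlated block consistently while margin-based elimination splits it
arbitrarily, so the PLS-DA lists are systematically more stable than the
R-SVM lists — the qualitative ordering the package asserts.

## DELFIA generator and the mean + 1 SEM rule

The positivity threshold HD mean + 1 SEM is intrinsically weak for
continuous, symmetric noise: for any iid continuous HD sample, roughly
40–45% of HD values exceed their own mean + 1 SEM, making specificities
near 100% unreachable. High observed specificities imply an HD
distribution that is an *atom-like flat background plus sparse high
values*. The generator models exactly that: non-reactive sera read the
flat plate background (times ~2% well noise, duplicate wells averaged),
a `sticky_rate` = 0.15 fraction of sera add an exponential uplift
(polyreactive/sticky sera), and reactive sera multiply the background by
`exp(N(log 8, 0.4))`. The sticky sera in the HD reference push the
threshold safely above the background plateau (the rate is chosen so a
35-donor reference group contains sticky members with probability
>99.7%); called sensitivity then tracks the designed reactivity rate
plus a small (~5–8 point) sticky contamination, and specificity lands in
the realistic 85–95% range. With `sticky_rate = 0` and zero well noise
the threshold equals the background exactly and the strict rule calls
every non-reactive serum negative — the idealized limit used in unit
tests.

ROC curves are empirical staircases over all distinct cut-offs (call
positive at score ≥ cutoff); trapezoid AUC equals the rank-sum pairwise
estimate with ties counted half, verified against an exhaustive pairwise
oracle and against scikit-learn as independent routes. Best cut-off
maximizes Youden J, ties resolved toward higher specificity. Two
combination modes exist because call-level (or-rule) and score-level
(summed HD z-scores) panels answer different questions; outputs label
the mode explicitly. χ² is used without continuity correction by
default (configurable), with a Fisher fallback when any expected count
is below 5.

## Problem sizes and determinism

Default study conditions: discovery 15 AIH / 78 HD arrays of 1626
antigens in quadruplicate; R = 50 subsets; k = 10 folds; N = 1000
permutations; validation 40 AIH / 35 HD / 95 VH. The full discovery +
validation run completes in well under a minute on one CPU. Heavier
simulation suites (permutation calibration, stability direction) use the
sizes stated in their tests. A single global seed expands into fixed,
named per-stage seeds via `SeedSequence`; manifests carry no timestamps,
so identical config + seed reproduces every output byte for byte.

## Known limitations

* The generator's recognition model is antigen-independent given the
  copula factor; real autoantibody repertoires have richer dependence.
* The LAD normalization assumes an affine relation between arrays on the
  ratio scale; saturation or nonlinear scanner response is not modelled.
* The consensus rule's strict 100% relative frequency is brittle at
  marginal effect sizes by construction; that behavior is inherited from
  the selection rule itself, not a software choice.
* R-SVM uses a fixed C = 1; no per-subset hyperparameter tuning.
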