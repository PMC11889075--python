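# Methods

## Setting and estimand

Data are two-point panels: individual i is observed at a baseline visit
(t=0) and a follow-up visit (t=1), with treatment T, confounders X, outcome
Y recorded at each visit, and an optional mediator.  The estimand is the
average treatment effect ATE = E_X[E[Y(1)|X] − E[Y(0)|X]] under strong
ignorability (exchangeability given X, and positivity 0 < P(T=1|X) < 1) and
SUTVA.  The difficult design is the all-treated-at-follow-up panel
(`lcd_like`): T is the visit indicator, so there is no control group, the
pooled 2n-row cross-section violates no-interference (both rows of an
individual enter as if independent), and the differenced data violate
positivity (ΔT ≡ 1).

## The subsample-randomization estimator

A subsample assigns every individual to exactly one of their two visits.
Two schemes are provided: `iid` (each visit with probability 1/2,
the default) and `balanced` (per individual, a random permutation of
⌊M/2⌋ zeros across the M subsamples — a Latin-hypercube-style balance that
minimizes pairwise subsample overlap).  Each subsample is a cross-section
with treated and untreated units; a matched ATE is computed per subsample
and the estimator is the plain average over M subsamples.  The average
equals the mean of the per-subsample ATEs by construction, and the test
suite asserts this identity to 1e-12.

### Matching

Per cross-section: maximum-likelihood logistic regression of T on [1, X]
(a Newton/IRLS solver on raw arrays; the estimator refits this model inside
every subsample and every permutation shuffle, so per-call overhead matters
— the solver is validated against scikit-learn's reference fit in the unit
tests).  Every unit is matched to the nearest opposite-group unit by
absolute propensity-score distance, with replacement, ties broken by lowest
unit index (deterministic, seed-free).  Matching runs in both directions so
all units contribute, targeting the ATE.

Matched imputations carry a **regression bias correction**: linear outcome
models fit separately on controls and treated (OLS of Y on [1, X]) shift
each matched outcome by μ̂(X_i) − μ̂(X_j).  This removes the first-order
error from the covariate discrepancy between a unit and its match.  The
correction is essential, not cosmetic: one-dimensional score matching
leaves an O(n^{-1/2}) covariate imbalance, and in panels whose outcome
depends strongly on a continuous confounder (an age coefficient of 1 per
year, age SD 10) plain 1-NN matching carries a bias of +0.3 to +0.6 at
n=100–200 and a per-subsample ATE noise dominated by the rare matches that
cross the binary-confounder boundary.  With the correction the bias is
statistically zero, the per-subsample ATE spread collapses by a factor ~5,
and every benchmark property documented below emerges.  The correction is
skipped automatically for groups with no more units than regression
parameters, and `bias_adjust=False` exposes the raw matching arithmetic
(used by the brute-force oracle tests).

Degenerate inputs: a one-class cross-section raises `PositivityError`;
perfect separation in the propensity fit triggers one ridge-stabilized
refit (ridge 1e-2, logged once per process) that keeps scores strictly
inside (0,1) and preserves their ordering; constant covariate columns fold
into the intercept.

### Permutation inference

Within each subsample the treatment vector is permuted uniformly (treated
count preserved), the propensity model refit, the sample rematched, and the
ATE recomputed; with S shuffles the p-value is (1 + #{s: |ATE⁽ᵐ'ˢ⁾| ≥
|ATE⁽ᵐ⁾|}) / (S+1).  Two design choices here are the package's own: the
comparison is **two-sided on |ATE|** (a one-sided "exceeds" rule would
assign p ≈ 1 to strong negative effects) and **add-one smoothed** (p = 0 is
never reported; the floor is 1/(S+1)).  S defaults to 200.  Because
subsamples overlap, the M p-values are dependent; the package reports their
distribution and uses "median p < α" as its rejection convention rather
than combining them into one number.  Under a true null the pooled
p-values are approximately U(0,1) (asserted by a KS check in the tests);
under the δ=1 study conditions at n=500 all subsample p-values fall below
0.05.

The permutation and subsample-assignment streams are derived from
(seed, subsample index) only — never from the covariate set — so two runs
with the same seed share assignments and shuffles exactly.  The mediation
decomposition depends on this contract.

## Benchmarks

* **Pooled matching**: both visits stacked into a 2n-row cross-section,
  matched on X (time is not a matching covariate).  Valid-looking but
  interference-laden when T is the visit indicator; in the Monte-Carlo
  comparison its variance (and hence MSE) exceeds the subsample
  estimator's, with both nearly unbiased.
* **DiD with stacked synthetic control** (`lcd_like` only): control rows
  (Y_{i,0}, T=0, covariates X_{i,0}) stacked against treated rows
  (ΔY_i, T=1, covariates ΔX_i), then matched.  The construction is kept
  exactly as its defining equations state it, including the
  covariate-meaning mismatch between the two row types (baseline levels vs
  differences); the mismatch makes the propensity model separable and the
  estimator badly biased, which is precisely its documented role as the
  inferior benchmark.
* **Group-construction DiD** (two-sided treatment changes): individuals are
  classified by treatment history (never / always / untreated→treated /
  treated→untreated); the always and treated→untreated groups are dropped,
  untreated→treated is matched against never-treated on baseline
  covariates with ΔY as the outcome.  Because both visits' treatments move
  the outcome, this estimator cannot recover the per-visit effect — also a
  documented failure mode, asserted as such.
* **First-difference analysis**: all variables differenced, confounders
  taken at baseline, treatment derived by rule: `delta_lcd` (everyone
  treated), `delta_bmi_negative` (the rule column decreased), or
  `delta_bmi_below_median` (decrease exceeding the median magnitude of
  change, Δ < −median|Δ|, which splits an all-decreasing sample into equal
  halves; ties at the threshold go to control).  For the first two rules a
  hypothetical control group of equal size with zero outcome and
  confounders bootstrap-resampled from the observed baselines restores
  positivity (the causal contrast then reduces to E[Y(1)|X]).  The
  permutation p-value shuffles treatment labels over the assembled
  cross-section, real and hypothetical units together — shuffling only the
  real units would be the identity permutation under `delta_lcd` and make
  the test vacuous.

## Mediation

Under a linear outcome model with no treatment–mediator interaction, total
= direct + indirect.  The total effect matches on the confounders; the
natural direct effect adds the mediator to the matching set (stratifying on
the mediator closes the mediated path; matching the confounders closes the
back-door paths that conditioning on the mediator opens).  The indirect
effect is the difference, computed subsample-by-subsample and
permutation-by-permutation on shared assignments and shuffles, so the
decomposition identity holds exactly at every level (asserted to 1e-12)
and the indirect effect inherits a permutation p-value.  No
nested-counterfactual imputation is attempted — the additive decomposition
is exactly the linear no-interaction scope of the method.  Ordinal
treatments (e.g. BMI categories <25 / [25,30) / [30,35) / ≥35) are handled
by adjacent-pair contrasts: each subsample is restricted to units at the
two named levels, the higher level coded as treated.

## Synthetic data

`gen_panel` draws from the structural model Y = α + δT + Xβ [+ γZ] + ε,
ε ~ N(0, σ²), with X = (age, binary group): baseline age ~ N(μ, σ_age²),
follow-up age = t_i + ρ·age₀ + √(1−ρ²)·ξ with a Unif{1..24}-month visit
gap t_i entering only the age equation, and the binary covariate constant
across visits.  Treatment is the visit indicator (`lcd_like`) or, per
visit, T ~ Bernoulli((1 + exp(Xβ_T [+ γ_T Z] + ε_T))⁻¹) with latent
N(0,1) noise *inside* the link and a decreasing link, exactly as the
generating equations are written (`bmi_like`).  The hidden confounder Z is
Bernoulli(p), redrawn independently at each visit, kept in the panel only
for oracle checks.  Defaults mirror the validation studies: μ=40,
σ_age=10, ρ=0.9, β=(1,1), β_T=(1/40, −1), γ=1, γ_T=−0.5, δ=1; p defaults
to 0.5 (the studies do not state it).  Identical config + seed reproduces
a panel bit-for-bit.

`gen_nutrition_like` emulates the *structure* of a two-visit primary-care
nutrition study (n=256 in the real setting): gender, age, a continuous BMI
mediator lowered by the diet (default −2 kg/m²), a 3-level ordinal
type-2-diabetes outcome thresholded from a latent HbA1c-like score, and a
continuous CVD-risk outcome with a direct diet path (−1) and a
BMI-mediated path (−2 × 0.4 = −0.8).  All path coefficients are
configurable and echoed in the panel metadata so tests can compare
recovered effects against the configured truth.  What it does **not**
emulate: missing data, measurement error, informative visit timing,
or any calibration to real summary statistics — so passing tests show the
pipeline recovers known effects under its own assumptions, not that those
assumptions hold in any particular clinic's data.

## Monte-Carlo studies and problem sizes

`run_grid` draws R panels per (n, σ) cell, records each method's estimate,
and reports MSE / bias² / variance against the true δ (population formulas;
MSE = bias² + variance to 1e-10 by construction).  Per-replicate seeds are
spawned from (master seed, cell index, replicate index), so every cell is
independently re-runnable.  The subsample-count study holds one n=500 panel
fixed and reruns the estimator with fresh subsample randomness, so the
reported variance is the subsample-randomization variance — the component
that provably shrinks as M grows; with fresh panels per replicate the
panel-level sampling variance (~4e-3) would swamp the M-dependent part
(~5e-5) and the monotonicity would be invisible at any affordable R.  The
null-calibration study reports the median-p rejection rate at α and the KS
distance of pooled p-values from U(0,1).

Sizes used by the shipped test suite (chosen to keep the full run at a few
minutes while leaving every comparison well inside its Monte-Carlo
resolution): single-sample inference at n=500 with M=120, S=150; the
pooled/DiD comparison grids at R=60 with M=150; the hidden-confounder study
at its full n=1000, R=200; the subsample-count study at M ∈ {100, 2000},
R=50; null calibration at R=100, M=10, S=120.  The acceptance script runs
the single-sample setup at full M=500.

## Known limitations

- The mediation operationalization is valid only under linearity and no
  treatment–mediator interaction; interaction-robust estimands are out of
  scope.
- No analytic variance or confidence interval for the subsample estimator
  is provided; inference is purely permutation-based.
- Hidden confounding is not corrected, only studied: under the
  hidden-confounder generator the estimator's bias does not vanish with n
  (≈ +0.10 at the default γ=1, γ_T=−0.5, p=0.5), and because the hidden
  variable is independent of the observed covariates that bias is identical
  for every X-adjusted estimator in the package — the pooled benchmark is
  neither better nor worse there.
- Matching is 1-NN on the propensity score only, with an off-by-default
  caliper option; Mahalanobis, exact and coarsened matching and
  inverse-probability weighting are not implemented.
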