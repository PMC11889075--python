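# irand

Causal inference for **two-point panel data without a control group**.

Routine clinical and observational studies often record each individual at
exactly two visits — a baseline and a follow-up — with an intervention
(a dietary change, a treatment program) started in between for *everyone*.
Such data have no contemporaneous control group: treatment is determined by
time, so pooling both visits violates the no-interference assumption, and
difference-in-differences has no untreated group to difference against
(P(ΔT=1|X) = 1 breaks positivity).

This package implements the **subsample-randomization estimator (I-Rand)**
for exactly this setting, together with the benchmark estimators it is
usually compared against, a mediation-effect decomposition, and a
Monte-Carlo framework for validating all of them on synthetic panels.

## The estimator

For a panel of n individuals observed at visits t ∈ {0, 1}, draw M
subsamples, each containing **every individual at exactly one visit**
(chosen at random).  Each subsample is a cross-section mixing treated and
untreated observations, restoring positivity while keeping one observation
per individual (no interference).  On each subsample m:

1. fit a logistic propensity model e(X) = P(T=1|X);
2. match every unit to its nearest opposite-group unit on e(X) (1-NN, with
   replacement, both directions — targeting the ATE, not the ATT);
3. impute each unit's missing potential outcome from its match, with a
   regression bias correction (within-group linear outcome models evaluated
   at the unit's and the match's covariates);
4. average the imputed unit-level effects → ATE⁽ᵐ⁾.

The overall estimate is the average

    ATE = (1/M) Σₘ ATE⁽ᵐ⁾

and significance comes from a permutation test inside each subsample:
shuffle the treatment labels (preserving the treated count), refit, rematch,
recompute; the p-value is the add-one-smoothed fraction of shuffles whose
|ATE| reaches the observed one.  Because subsamples overlap, the M p-values
are dependent and are reported as a distribution (median, IQR, fraction
below α) rather than combined.

Also included:

- `pooled_ate` — match on the stacked 2n-row sample (the pooled benchmark);
- `did_stacked_lcd` — difference-in-differences with a stacked synthetic
  control built from the baseline rows;
- `did_bmi_like` — group-construction DiD for treatments that switch either
  way between visits;
- `did_firstdiff` — first-difference analysis with derived threshold
  treatments and hypothetical zero-outcome controls;
- `total_effect` / `direct_effect` / `indirect_effect` — mediation
  decomposition (total = direct + indirect under a linear no-interaction
  model), with shared subsample assignments and permutation draws so the
  identity holds exactly, permutation by permutation;
- `gen_panel` / `gen_nutrition_like` — synthetic panel generators;
- `run_grid`, `hidden_confounder_study`, `subsample_count_study`,
  `null_calibration_study` — Monte-Carlo validation studies.

## Worked example

```python
from irand import DGPConfig, gen_panel, irand_estimate, summarize_pvalues

cfg = DGPConfig(n=300, sigma=1.0, delta=1.0, treatment_design="lcd_like", seed=7)
panel = gen_panel(cfg)                      # everyone treated after baseline
res = irand_estimate(panel, M=200, S=100, seed=1)
print(res.estimate)                         # 1.123
print(summarize_pvalues(res, alpha=0.05))
```

prints (from `examples/01_estimate_without_control_group.py`):

```
true effect:            1.0
I-Rand estimate:        1.123   (mean of 200 subsample ATEs)
subsample ATE spread:   0.112
p-values: median=0.0099  frac<0.05=1.00  reject H0: True
```

Although no individual is ever observed untreated alongside a treated peer,
the estimate lands near the true effect of 1 and every subsample's
permutation p-value rejects the no-effect null at the 5% level.  The other
scripts in `examples/` walk through the benchmark comparison, the mediation
decomposition, the first-difference rules, and the null calibration.

A thin CLI mirrors the library:

```sh
irand simulate --design lcd --n 300 --seed 7 --out panel.csv
irand estimate --input panel.csv --m 200 --s 100 --seed 1
irand mediate  --input nut.csv --outcome cvd_risk --mediator bmi \
               --confounders age,gender
```

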