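# softwin

Soft windowing of temporally local controls for long-running phenotyping
studies.

## The problem

High-throughput phenotyping programmes — the motivating case is knockout
mouse phenotyping, where a small mutant group is compared against wild-type
controls — accumulate control data continuously for years. The control pool
is large, but its mean and variance drift over time (seasons, personnel,
equipment). A mutant line is measured in a few batches within weeks, so
comparing it against the entire multi-year control pool mixes in baseline
eras the mutants never saw, while a fixed hard time window discards data
and makes the control set depend on how long the line took to phenotype.

`softwin` assigns each observation a weight in (0, 1] that decays smoothly
with temporal distance from the mutant measurement dates and fits the
genotype–phenotype association by weighted regression. For each peak (mutant
measurement day) `m` the weight curve is

```
c(t) = F(t; m − l, k) · (1 − F(t; m + l, k)),        w(t) = 1 − Π_i (1 − c*_i(t))
```

with `F` a symmetric CDF (logistic by default), `l` the bandwidth in days,
`k` the edge sharpness in 1/days (`k → ∞` gives a hard window), `c*` the
max-normalized curve, and the product form merging overlapping windows by
inclusion–exclusion. The bandwidth and shape are tuned automatically: the
window expands along a log-spaced grid, admissible whenever its
sum-of-weights score reaches `T = max(35, π√n)` (single window) or `35p`
(`p` windows), and stops before the earliest Bonferroni-significant change
in mean (Welch t) or variance (F) of the fit residuals. The final model is
a weighted linear mixed model — genotype, sex, genotype×sex and body weight
as fixed effects, a random intercept per batch (measurement day), weights
as precision weights — with backward elimination of nonsignificant
covariates and a Wald test on genotype.

Validation machinery is included: a sensitivity analysis over the
minimum-observation threshold `T`, and structured resampling that relabels
the temporally closest controls as artificial mutants (preserving the
batch pattern of the true mutant group) to compare false-positive counts
with and without windowing. Everything runs on synthetic data generated by
the package itself.

## Worked example

```python
from softwin import (CohortSimConfig, GridConfig, inject_genotype_effect,
                     simulate_cohort, soft_window_pipeline,
                     effective_control_count)

# 400 controls over a year whose first 90 days are corrupted (mean +3,
# variance ×100); 8 mutants in two batches at days 280/287 carry a true
# effect of ~2.6 clean-era standard deviations.
cfg = CohortSimConfig(n_controls=400, n_mutants=8, span_days=365,
                      mutant_batch_days=(280, 287),
                      drift_segments=((0, 90, 3.0, 100.0),), seed=3)
data = inject_genotype_effect(simulate_cohort(cfg), 0.5)

result = soft_window_pipeline(data, GridConfig(n_l=30, n_k=10))
sel = result.selection
groups = data.data["group"].to_numpy()
print(f"selected window: l* = {sel.l_star:.1f} days, k* = {sel.k_star:.2f} per day (T = {sel.T:.0f})")
print(f"effective controls: {effective_control_count(result.windowed.weights, groups)} windowed"
      f" vs {effective_control_count(result.nonwindowed.weights, groups)} non-windowed")
print(f"genotype p-value: {result.windowed.genotype_p:.3g} windowed"
      f" vs {result.nonwindowed.genotype_p:.3g} non-windowed")
```

prints

```
selected window: l* = 161.8 days, k* = 1.89 per day (T = 70)
effective controls: 279 windowed vs 400 non-windowed
genotype p-value: 1.28e-07 windowed vs 0.369 non-windowed
```

The tuner stops the window right at the corrupted era's edge (the mutants
sit at day ~283; 283 − 162 ≈ 121 > 90), keeping 279 of the 400 controls
effectively in the analysis. Against those temporally local controls the
injected effect is obvious (p ≈ 1e-7); the non-windowed fit dilutes its
variance estimate with the noisy era and misses it entirely (p ≈ 0.37).

## Command line

```
softwin simulate --scenario cohort --seed 3 --drift 0:90:3.0:100.0 --out cohort.csv
softwin analyze --input cohort.csv --out run/          # report.json, weights, trace
softwin sensitivity --input cohort.csv --out run/      # genotype p across T
softwin resample --input cohort.csv --repeats 5 --out run/   # FP comparison
```

`analyze` writes a JSON report with both genotype p-values, the selected
(l*, k*), effective control counts and the full selection trace; input is
any delimited table with date, response and group columns (IMPC-style
column names are the default, remappable via flags).

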