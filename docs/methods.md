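# Methods

## The problem

Long-running phenotyping programmes (the motivating case is high-throughput
mouse phenotyping, where knockout lines are compared against wild-type
controls) accumulate control data over years. Controls are measured with
nearly every experimental batch, so the control pool is large — but its mean
and variance drift with seasons, personnel, equipment and husbandry changes.
A mutant line, by contrast, is typically measured in a handful of batches
inside a few weeks. Comparing a temporally concentrated mutant group against
the entire multi-year control pool mixes in baseline eras the mutants never
experienced; restricting to a fixed hard time window throws data away and
makes the effective control set depend arbitrarily on how long the mutant
line took to phenotype.

Soft windowing replaces the binary include/exclude decision with a weight in
(0, 1] per control observation that decays smoothly with temporal distance
from the mutant measurement dates, and fits the association model by
weighted regression.

## Weight-generating function

Let `t` be observation times (days since the earliest observation; input
dates are parsed to timestamps and rebased, which keeps the arguments of the
exponentials small), and `m_1 < … < m_p` the peak locations — the distinct
mutant measurement days. Each peak contributes a curve

```
c_i(t) = F(t; m_i − l, k) · (1 − F(t; m_i + l, k))
```

where `F` is a symmetric, continuous CDF (logistic by default; Gaussian,
Cauchy and Laplace are available), `l ≥ 0` is the bandwidth (half-width in
days) and `k > 0` the shape. `k` acts as a *rate*: the effective scale of
`F` is `1/k`, so `k → ∞` produces a hard rectangular window on
`[m_i − l, m_i + l]` and small `k` a diffuse one. Each curve is normalized
by its maximum over the observed grid (`c*_i = c_i / max c_i`), so a single
peak always attains weight exactly 1 somewhere on the data. Peaks are merged
by inclusion–exclusion, computed in the closed form

```
w(t) = 1 − Π_i (1 − c*_i(t)),
```

which is algebraically identical to the alternating sum over peak subsets
(the tests verify this against a brute-force expansion for p ≤ 4).
Overlapping windows therefore fuse into one plateau and the combined weight
never drops below any constituent curve. Weights are floored at 1e-12 so
strict positivity holds in floating point; the separate reporting cutoff for
"effectively included" controls is 1e-7.

## Weighted model

The association model is the phenotyping standard: fixed effects for
genotype, sex, genotype×sex and body weight (terms degenerate in the data —
single-sex cohorts, constant or mostly-missing body weight, single-sex
mutant groups — are dropped with a logged note; body weight with ≤ 50%
missing values is mean-imputed so rows are not silently deleted), plus a
random intercept per batch, where a batch is the set of measurements taken
on one calendar day. Weights enter as precision weights: observation `i`
has residual variance `σ²/w_i`, exactly the meaning of lme4's `weights`
argument.

The weighted least-squares fit uses the closed form
`β̂ = (X'WX)⁻¹X'Wy` (via statsmodels WLS). The weighted mixed model is
fitted by an exact profiled REML computation written here: with one random
intercept per batch the marginal covariance is block-diagonal, each block a
diagonal plus a rank-one term, so for any variance ratio `λ = τ²/σ²` the
GLS solution, the restricted likelihood and `σ̂²` are available in closed
form (Sherman–Morrison); `λ` is then found by bounded scalar search with an
explicit check of the `λ = 0` boundary. The implementation reproduces lme4
(`lmer(y ~ … + (1|batch), weights = w, REML = TRUE)`) to all printed digits
and statsmodels MixedLM at unit weights; both serve as independent oracles
in the test suite. Inference on every term is a two-sided Wald test; the
conventional significance threshold in production pipelines, 1e-4, is a
reporting default only.

Rows whose weight is below 1e-7 times the maximum weight are excluded from
fitting. This matters: retaining them would count non-informative rows in
the residual degrees of freedom and, in the mixed model, let their
near-zero residuals drag the variance estimate toward zero — measured on a
corrupted-era fixture this produced order-of-magnitude anti-conservative
genotype tests. The relative cutoff preserves the scale-invariance of the
weighted estimator. Model reports still carry residuals and fitted values
for every row.

With fewer than two effectively included batches the random effect is
unidentifiable and the fit degrades to WLS with a note. Backward
elimination iteratively removes the least significant removable term with
p > α (default 0.05), refitting after each removal; the genotype effect and
the intercept are never removed, and the sex main effect only becomes
removable once the genotype×sex interaction is gone. The batch random
effect is always retained when identifiable.

## Tuning the window

One symmetric bandwidth `l` and shape `k` are shared by all peaks (a
2p-dimensional asymmetric search is representable but never performed).
Candidate bandwidths are log-spaced (500 by default) from 1 day to the
total experiment range; candidate shapes are 50 log-spaced values in
[0.5, 10] per day.

A candidate is *admissible* if its sum-of-weights score
`SWS(l, k) = Σ_i w_i` — a weighted effective sample size satisfying
`SWS(l, k) ≥ T(l)` (the hard-window count), with equality as `k → ∞` —
reaches a minimum threshold `T`. By default
`T = max(35, π√n)` for a single window and `35·p` for `p` windows,
echoing the z-test minimal-sample heuristic (n > 30). `p` here counts
*windows*, not measurement days: peaks closer than 7 days (the typical
spacing of a line's consecutive batches) merge into one window for any
useful bandwidth, so they count once. Without this, an artificial mutant
group scattered over six adjacent days would demand `T = 210` and force the
window over the entire series. If `T` exceeds n the constraint is
unsatisfiable and the analysis proceeds non-windowed with a warning.

The bandwidth search expands `l` through the admissible grid while `k` is
held at 2 (the geometric middle of the shape range). At each step the model
is refitted with the candidate weights; the residuals of observations newly
entering the hard-window support — pooled across steps until at least three
(and at least 5% of the vetted support) are available, so that fine grids
do not dilute the test — are compared against the residuals of the
previously admitted support from the same fit, with a Welch t-test (mean
change) and a two-sided variance-ratio F-test (variance change). The
selected `l*` is the last grid value before the earliest change that is
significant after Bonferroni correction over all performed tests (two per
comparison); if no change is ever declared, `l*` is the largest admissible
bandwidth and the whole series is effectively included. Testing new
arrivals against the vetted set, and stopping at the earliest significant
change, is what makes the selected support exclude a corrupted era: a
full-set-versus-full-set comparison dilutes the signal of the first few
corrupted admissions, and a "most significant change" rule fires only after
the era has partially entered the window.

The shape is then tuned at the fixed `l*` by walking the admissible shape
grid from its hard end toward softer values and comparing consecutive
within-support residual sets the same way; the scan stops before the first
significant change (softening only leaks neighbouring noise into the fit,
so the value preceding the change is the last safe one). If nothing fires
— the common case — `k*` is the admissible value nearest the geometric
midpoint of the shape range, committing to neither extreme.

The search is deterministic: identical data and configuration give
identical selections.

### Sensitivity to T

`sensitivity_over_T` re-runs the full pipeline over 25 log-spaced values of
`T` from 14 to n and tabulates `(T, l*, k*, genotype p)`. The largest `T`
before a step change in the p-value — reported as the `T` at the largest
jump in −log10 p between consecutive rows — is the practical upper limit
("maximum toleration") before the constraint forces noisy eras into the
fit.

## Structured resampling and false positives

Because mutants are phenotyped in temporally clustered batches, a
false-positive experiment must replicate that structure. The true mutant
group's measurement-time offsets are slid to a uniformly random origin
within the control span (chosen so the whole pattern fits); each shifted
target time claims the temporally closest not-yet-taken control, ties
broken uniformly at random, until as many controls are relabelled as there
were mutants. Relabelled controls keep their true batch, so day-level
random-effect structure is real, not synthetic; true mutants are excluded.
Each artificial dataset is analysed twice — non-windowed and through the
full pipeline — and a genotype p-value below the threshold counts as a
false positive for that arm, aggregated as
`relative change = 100·WFP/(NFP+WFP)`.

A note on mechanism, established with the generator below: an era in which
only the control *mean* shifts produces essentially no false positives in
either arm, because the per-day random intercept absorbs day-level mean
structure (the batch variance inflates and the genotype test becomes more
conservative). The false-positive contrast between the arms is driven by
*variance* heterogeneity: artificial mutants landing in a high-variance era
are tested against a globally pooled — hence understated — residual
variance in the non-windowed fit, while the windowed fit estimates the
local variance. Validation fixtures therefore corrupt an era in both mean
and variance.

## Synthetic data

Two generators drive all tests and validation; no external data are used.

*Piecewise signal.* `y_t = t·β_j + ε`, `t = 1…60`, segment boundaries at
20 and 40 (`t ≤ 20`, `20 < t < 40`, `t ≥ 40`), β = (0, 1, 0), ε ~ N(0, 1).
A linear trend exists only in the middle segment; weighted regression with
a window centred there (l = 9, k = 5, m = 30) recovers the slope (mean
estimate ≈ 1.00, per-replicate SD ≈ 0.042 over 200 replicates), while the
global fit's slope sits near 0.02 — many standard errors away.

*Cohort generator.* Emulates the production setting at desk-runnable cost.
Defaults: 1500 controls accumulating over 730 days, measurement day drawn
uniformly (so roughly two controls per daily batch), 14 mutants split over
two batches seven days apart at ~60% of the span; response = baseline 10 +
N(0, 0.25²) day effect + 0.25·[sex = M] + 0.05·(centred body weight) +
N(0, 1) noise; body weight is linear in measurement day with sex offset and
noise. Configurable era segments apply a mean shift and/or variance
multiplier to the controls of an interval; a heavy-tail switch substitutes
unit-variance t₃ noise for outlier-prone procedures. An injected genotype
effect shifts mutant responses by a multiple of the pooled within-batch
control SD (computed from controls only, so injections compose additively).
Validation experiments use scaled-down cohorts — 400 controls over 200–365
days, 8 mutants, grids of 25–30 bandwidths and 10 shapes, 200–500
replicates — sizes chosen so the full suite runs in about a minute while
every rate estimate keeps a usable binomial standard error.

What the generator does *not* emulate: seasonal autocorrelation within
eras, centre-to-centre differences, informative missingness, litter
structure below the batch level, and procedure-specific distributions
beyond the single heavy-tail switch. Passing tests demonstrate the
machinery's behaviour under controlled drift and variance breaks, not
performance on any real phenotyping archive.

## Numerical choices and edge cases

- Weights are clipped to [1e-12, 1]; the single-peak grid maximum is exactly 1.
- `λ` (batch/residual variance ratio) is searched in [1e-8, 1e6] on a log
  scale with the zero boundary checked explicitly; `σ̂²` is floored at
  1e-300 to keep logs finite on degenerate inputs.
- Change tests require ≥ 3 values per side; identical constant sets score
  p = 1; a zero-variance side sends the F p-value to 0 (a variance change
  by any finite ratio is certain).
- Rank deficiency raises an error naming the collinear columns (greedy rank
  growth over the weighted design).
- Datasets spanning a single day, or failing the `SWS ≥ T` constraint at
  every grid point, are analysed non-windowed with a flagged, non-fatal
  fallback.
- Ties when several controls are equidistant from a resampling target are
  broken uniformly at random under the caller's seeded generator; all
  generators are pure functions of their configuration including the seed.

## Known limitations

- Wald p-values from the mixed model are asymptotic; with very small mutant
  groups the per-dataset rejection rate wobbles around the nominal level by
  about a percentage point (the permutation test in the suite quantifies
  this in aggregate).
- The earliest-significant-change rule inherits the grid's resolution: the
  finer the grid, the longer new admissions pool before a test, and the
  revert point can overshoot conservatively (never into the corrupted era,
  but possibly short of it).
- Selection and inference use the same data; no post-selection correction
  is applied to the final genotype p-value, matching production practice.
- The asymmetric per-peak parameterization is representable in
  `WindowSpec` but the tuner never searches it.
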