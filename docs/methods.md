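# Methods

## The problem

Decision curve analysis (DCA) compares clinical risk prediction models by
*net benefit*: at a threshold probability `p_t`, intervening on every patient
with predicted risk `p_d >= p_t` yields

    NB(p_t) = TP/n − (FP/n) · p_t/(1 − p_t) − harm,

in true-positive equivalents per patient.  A false positive is exchanged
against true positives at the odds of the threshold — exactly the exchange
rate a patient indifferent at `p_t` accepts.  The optional `harm` is a
constant per-patient cost of the intervention (no functional form is assumed
beyond a constant; per-patient harm functions are out of scope).

When two models' curves cross inside the clinically relevant threshold range
there is no pointwise winner.  The area under the net benefit curve (A-NBC,
trapezoidal) summarizes the range but implicitly assumes thresholds are
uniformly distributed across patients.  The package's central statistic, the
*weighted* area WA-NBC, integrates the curve against the actual distribution
of patient thresholds,

    WA-NBC = ∫ NBC(t) dF(t)  over the range of interest,

so model performance is weighted by how many patients genuinely hold each
threshold.

## Estimating the threshold distribution from binary decisions

Individual thresholds are unobservable, but routine data record the binary
decision `Z = I(p_d >= p_t)` together with `p_d`.  Assuming `p_t` is
independent of `p_d` across patients, the CDF `F(k) = P(p_t <= k)` satisfies
a self-consistency identity obtained by splitting the cohort on `(Z, p_d <= k)`:

* `Z = 1, p_d <= k`: then `p_t <= p_d <= k`, contributing 1;
* `Z = 1, p_d > k`: contributes `F(k) / F(p_d)` (the conditional probability
  of `p_t <= k` given `p_t <= p_d`);
* `Z = 0, p_d <= k`: contributes `1 − (1 − F(k)) / (1 − F(p_d))`;
* `Z = 0, p_d > k`: then `p_t > p_d > k`, contributing 0.

Averaging the contributions over the cohort gives an update map whose fixed
point is the estimate; iteration starts from the uniform CDF.  Two
implementation notes matter:

1. **The ratio denominators are per patient.**  Replacing `F(p_d_i)` by the
   cohort-average `P(p_t <= p_d)` looks equivalent in expectation but makes
   the identity only hold trivially for the exact-law version and, in the
   plug-in version, destroys the fixed point: the iteration then collapses to
   a step function (we verified this numerically; the residual of the truth
   under the aggregate update is ≈ 0.22 sup-norm at n = 10000).  Conditioning
   on each patient's own `p_d` keeps the identity exact under independence.
2. **Monotonicity is enforced every iteration.**  The raw update can exit
   [0, 1] or lose monotonicity at finite n; each iterate is clipped and
   projected onto nondecreasing sequences by pool-adjacent-violators
   (`scipy.optimize.isotonic_regression`).  Monotonicity also guarantees each
   patient-level ratio stays in [0, 1] with no ad-hoc clipping.

**Grid and interpolation.**  The CDF is estimated on 201 equally spaced
points on [0.005, 0.995]; between points (and at patient risks) it is
evaluated by linear interpolation anchored at F(0) = 0, F(1) = 1.

**Convergence.**  The sup-norm change between iterates decays roughly like
1/iteration down to a plateau set by the sampling noise of the empirical
terms (~1e-4 at n = 10000).  The default tolerance is therefore
`max(2e-4, 2/n)` — far below the estimator's statistical error (sup-distance
to the generating CDF is ~0.02–0.03 at n = 10000) — with a cap of 100
iterations.  Non-convergence is flagged on the result, never fatal.
Degenerate all-treat or no-treat cohorts raise an error: the distribution is
not identifiable from decisions that never vary.

Only the *distribution* of thresholds is identified; individual `p_t` values
are not, and the estimator's interface never sees them.

## Integration and weights

WA-NBC is computed as a Riemann–Stieltjes sum: each curve grid point owns
the cell between the midpoints to its neighbours, weighted by the CDF
increment across that cell.  With a uniform CDF this reproduces the
trapezoidal rule exactly, so WA-NBC ≡ A-NBC under uniform weighting (an
identity the tests assert at 1e-6).  Weights are deliberately *not*
renormalized over the range of interest: the statistic is the expected net
benefit restricted to thresholds in range, matching the integral as written.
A distribution with no mass in the range yields 0 with a warning.

Default grids: 101 equally spaced points across a range of interest;
full-range curves use step 0.001 on [0.001, 0.999].  The fine full-range
step matters for cohort totals (below): a 0.01 cutoff would discard
~n · 0.01 · prevalence ≈ 35 true-positive equivalents of threshold mass near
zero, visibly biasing the uniform-assumption total.  The `p_t/(1 − p_t)`
singularity at 1 is never evaluated.

## Comparison statistics and the paired bootstrap

For two models the statistic is always model 1 minus model 2:

* **C-NBC** (standard): pointwise percentile bootstrap CIs for the curve
  difference; equivalence at a threshold iff the CI contains zero.  Rates
  over a range are the per-threshold rejection indicators averaged across
  the grid.
* **A-NBC**: trapezoidal area difference, one CI.
* **WA-NBC**: Stieltjes-weighted difference, one CI.

Both models are evaluated on the *same* bootstrap resamples (rows of
`(y, p_d1, p_d2)` resampled jointly), which preserves pairing and shortens
the CI of the difference.  Models are fit once on the original data and not
refit per resample; the threshold CDF used by WA-NBC is likewise estimated
once from the full data — from `(Z, p_d)` of a designated reference model,
model 1 by default — and held fixed across resamples, so the weight function
is not a source of bootstrap variation (a `cdf_policy="per_resample"` switch
re-estimates it inside every resample for sensitivity analysis; in our
experiments it changes power by only a few points).  CIs are percentile
intervals at `alpha/2` and `1 − alpha/2` with linear interpolation between
order statistics; defaults `n_boot = 1000`, `alpha = 0.05`.  Decisions:
model 1 superior iff `ci_lo > 0`, model 2 superior iff `ci_hi < 0`,
equivalent otherwise.  Identical inputs and seed reproduce CIs bit for bit.

## Cohort totals

The "total net benefit" summarizes a model for a whole cohort in
true-positive-equivalent counts.  Three accountings are implemented
(the definition is verbal in the source material; this operationalization is
the package's):

* **true thresholds** — Σ over patients of the cohort curve linearly
  interpolated at each patient's own `p_t` (simulation ground truth only);
* **estimated distribution** — n × the Stieltjes integral of the curve
  against the recursively estimated CDF over (0, 1);
* **uniform distribution** — n × the trapezoidal area over the full grid
  span (exactly n × A-NBC by construction).

## The synthetic cohort generator

The generator emulates prostate-cancer cohorts facing the
seminal-vesicle-invasion (SVI) decision:

| quantity | law | default |
|---|---|---|
| PSA | Exponential, rate 0.1 (mean 10 ng/ml) | fixed |
| Gleason score GS | 2 + Bin(4, ½) + Bin(4, ½), range 2–10, mean 6 | fixed |
| X1 (BMI-like) | Normal(27, 6) | fixed |
| n1…n6 | iid standard normal noise predictors | fixed |
| outcome | logit(p_d) = −10 + 0.1·PSA + 0.2·X1 + 0.5·GS | configurable coefficients |
| power scenario | adds γ·n1 + ε, ε ~ N(0, noise_sd²) | γ ∈ {0.3, 0.35, 0.4}, noise_sd = 1 |
| thresholds p_t | Beta(2, 7) / uniform / Exp(10) truncated at 1 | Beta(2, 7) |
| decision | Z = I(p_d_true ≥ p_t) | exact |

Monte-Carlo prevalence of the base model is 0.393 (n = 10⁶).  The noise
term's scale is genuinely unspecified by the study design; `noise_sd = 1` is
the conventional reading and the default, with the sensitivity of the power
estimates documented below.  Default study scale is 1000 replicates of
n = 10000; every experiment takes a replicate override, and scaled runs
report Monte-Carlo standard errors alongside every rate.

What the generator does *not* emulate: correlated predictors, calibration
drift between training and deployment, informative missingness, or any
dependence of `p_t` on covariates (the estimator assumes `p_t ⊥ p_d`).
Passing tests therefore demonstrate internal validity of the statistics
under these idealized conditions, not robustness on real cohorts.

## Experiments and observed behaviour

* **Type-I error** (equivalent models with disjoint noise predictors): all
  three statistics reject near or below the nominal 5% (measured ~0.03–0.05
  at n = 10000).
* **Power** (model 1 carries the causal `n1` that model 2 omits, range
  0.30–0.50): the weighted statistic dominates the pointwise standard at
  every effect size, and power is monotone in γ.  Sensitivity to the
  unspecified noise scale, measured over noise_sd ∈ {0, 0.5, 1} at 60
  replicates each: WA-NBC power moves by up to ~0.10 and C-NBC by up to
  ~0.18 relative to the noise_sd = 1 value.  Note that the absolute power
  levels of the area statistics in this implementation are substantially
  higher than those reported for the original design (see the repository's
  acceptance outputs); the ordering and calibration claims all reproduce.
* **Estimator convergence**: for Beta(2,7), uniform and truncated-
  exponential truths at n = 10000, the estimate converges within 100
  iterations and lands within sup-distance 0.05 of the generating CDF in
  ≥ 95% of replicates.
* **Cohort totals**: with uniform thresholds all three accountings agree
  (~1685–1695); with Beta(2,7) thresholds the estimated-distribution total
  tracks the true-threshold total to <0.2% while the uniform assumption
  underestimates it by ~40%.
* **Crossing example** (PSA-only logistic vs the rule I(GS ≥ 6 and
  X1 > 25), range 0.15–0.45): the curves cross in range; A-NBC declares
  equivalence in the large majority of replicates while WA-NBC declares the
  logistic model superior in the majority, because the right-skewed
  threshold distribution concentrates patients where that model dominates.
  The rule-based model is used as a {0, 1}-valued risk score directly
  (`m2_mode="fitted"` instead fits a logistic on the indicator, which
  collapses to two risk levels anyway).

## Numerical choices and degenerate inputs

* Classification ties treat `p_d >= p_t` as positive, matching the decision
  rule that generates `Z`.
* Percentile CIs use linear interpolation between order statistics; an
  `n_boot < 2/alpha` warning flags unstable tail quantiles.
* Bootstrap resampling draws row indices from a seeded
  `numpy.random.Generator`; replicate seeds are spawned deterministically
  from the master seed via `SeedSequence`.
* Empty cohorts, length mismatches, non-binary outcomes/decisions,
  out-of-range risks and thresholds at 0 or 1 raise typed errors
  (`InputError`/`DomainError`); all-treat or no-treat cohorts raise
  `DegenerateDecisionsError` from the CDF estimator.
* The experiment drivers fit with `statsmodels.Logit` (Newton); separation
  or degenerate outcomes raise `FitError` and the replicate is skipped and
  counted.

## Problem sizes used in the shipped tests and acceptance script

Cohorts are always n = 10000 (the study condition).  The test suite runs
200 replicates for the type-I, power and totals experiments and 100 for
convergence and the crossing example, with 200 bootstrap resamples; the
acceptance script uses 300 replicates.  Monte-Carlo standard errors are
reported with every rate so scaled runs remain interpretable.
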