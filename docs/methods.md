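# Methods

## State space and classification

The five MetS components are evaluated from raw measurements with the
revised AHA/NHLBI consensus criteria and Asian waist cutoffs:

| component          | criterion (men / women)                         |
|--------------------|--------------------------------------------------|
| abdominal obesity  | waist > 90 cm / > 80 cm                          |
| high TG            | TG ≥ 150 mg/dl                                   |
| low HDL            | HDL < 40 / < 50 mg/dl                            |
| high BP            | systolic ≥ 130 **or** diastolic ≥ 85 mmHg, or on antihypertensives |
| high FPG           | FPG ≥ 100 mg/dl, or on antidiabetics             |

Boundary convention: the consensus definition uses inclusive (≥) cutoffs
for TG, BP and FPG, and that is the default here; some descriptions read
"more than", so `ThresholdPolicy(strict=True)` switches those three to
strict (>). HDL is always strictly below its cutoff and waist strictly
above, which no convention disputes. Lipid-lowering medication is *not* a
criterion for high TG / low HDL — medication use for those components is
typically not captured in the source data, and including it would change
the phenotype definition.

The 32 component profiles partition into the 8 states as 1 (none) + 5
(isolated) + 10 (any pair → the pooled 2-component state) + 16 (≥3 →
MetS). Pooling pairs discards which pair occurred; this is the price of an
8-state chain over a 32-state one, and it is what the published transition
matrices encode.

## Transition estimation

Input is a two-wave panel: per subject, baseline state, follow-up state and
the inter-wave interval in years. The estimator is

1. `n_ij` = number of subjects observed moving from state *i* to *j*;
   person-years for row *i* = sum of intervals of subjects starting in *i*;
2. annual incidence rate `r_ij = n_ij / person-years_i` (off-diagonal);
3. annual probability `P_ij = 1 − exp(−r_ij)`; diagonal as the residual
   `1 − Σ_{j≠i} P_ij`, which makes each row sum to 1 exactly.

Assumptions and conventions:

- **Person-time attribution.** Each subject contributes their whole
  interval to their *baseline* state. With only two observation waves the
  intermediate path is unobserved, so this is the simplest estimator
  consistent with an annual incidence rate; it understates time at risk in
  states entered mid-interval. A config switch substitutes the panel-mean
  interval for every subject, matching analyses that report only a mean
  follow-up.
- **Per-cell annualization, not matrix-log embedding.** Each cell is
  annualized independently with the exponential formula. Deriving an annual
  matrix whose 5th power equals the observed 5-year matrix (the embedding
  problem) is deliberately out of scope; the per-cell conversion is the
  estimator the published matrices were built with, and the residual
  diagonal absorbs the inconsistency. Rows whose off-diagonal probabilities
  sum past 1 are rejected rather than rescaled.
- **Zero cells.** A transition never observed gets probability 0. An
  optional continuity correction adds 0.5 events to zero off-diagonal cells
  of rows with follow-up time (published tables containing 0.01% entries
  suggest some such smoothing); it is off by default because it biases
  recovery simulations.
- Sex strata are estimated fully separately; no pooled matrix exists.

## Printed-matrix loading

The bundled fixtures carry the two published sex-specific matrices
bit-exact as percentages. Rows printed to 2 decimals sum to 99.83–100.44%,
not 100; each row is divided by its own sum on load (original sums are
logged). Renormalization moves entries by at most ~0.37 pp (women's
isolated-low-HDL row); projections refuse unrenormalized matrices.

## Projection

Occupancy after *k* cycles is the initial vector times the *k*-th matrix
power, computed by repeated vector–matrix products with a per-step
renormalization guard against floating-point drift (the guard is inactive
to ~1e-16 for valid matrices). Horizons are whole years — the model has an
annual cycle and no half-cycle correction, consistent with year-1
projections that equal the matrix row itself. Correctness is checked by
probability conservation, the Chapman–Kolmogorov property at 1e-12, and
convergence toward the stationary left eigenvector.

Reproduction tolerance: multi-year projections are compared with published
values at ±0.5 pp, since 2-decimal rounding of matrix entries compounds
over 15 multiplications; year-1 occupancies equal the renormalized matrix
row exactly, and the printed row to within 0.01 pp (renormalizing a row
printed to 2 decimals shifts entries by up to ~0.01 pp, so agreement
tighter than that is not attainable from the printed table).

## Microsimulation

Sampling uncertainty around a projected occupancy is obtained by
individual-level Monte Carlo: each of `n` individuals draws their next
state every year from their current state's matrix row; the cohort is
replicated `R` times and the interval is the nonparametric percentile
interval (default 95%) of the per-replicate occupancy proportions, with the
replicate mean as point estimate. Defaults: n = 10,000, R = 200.

Because individuals are exchangeable given their state, the implementation
draws one multinomial count vector per occupied state per year rather than
looping individuals — distributionally identical and fast enough for
100,000-individual checks. One seed drives a run; replicate substreams are
spawned deterministically (`numpy` `SeedSequence`), so any replicate is
reproducible in isolation.

The interval method is a package choice: published intervals for this kind
of model rarely state their construction, so printed interval bounds are
treated as plausibility references only. Our intervals are instead
validated by coverage simulation: across 200 independent replicate-sets
under a known matrix, the 95% interval contains the analytic (matrix-power)
occupancy in at least 90% of sets.

## Synthetic cohorts

The generator emulates a two-wave population panel with known ground truth:
baseline states are drawn from a configurable distribution, follow-up
states from the true annual matrix compounded over `round(interval)` yearly
cycles (default interval 5.4 years → 5 cycles, mirroring a mean follow-up
of about five years in a cohort of a few thousand young adults). The
annual-cycle model cannot generate fractional-year dynamics, hence integer
compounding; an optional ±0.5-year jitter perturbs the *recorded* intervals
to emulate field-visit scheduling noise. All draws are tallied into an
audit object so estimation tests compare against the actual draws, not just
their expectation.

Raw measurements for a requested state are drawn from truncated normal
windows that stop half a unit clear of every diagnostic cutoff, so
classification round-trips exactly under either boundary convention; the
abnormal component subset for the pooled states is uniform over valid
subsets. The windows are package constants chosen as clinically plausible
young-adult ranges (e.g. normal systolic 95–127 mmHg around 112, abnormal
133–180 around 144); they are *not* fitted to any cohort's descriptive
statistics. Consequently the generator reproduces threshold consistency but
not the joint correlation structure of components, within-person drift, or
medication-treated physiology — passing round-trip and recovery tests shows
the pipeline is self-consistent, not that real cohorts meet the model's
assumptions.

Parameter-recovery checks use a 1-year generation interval so the generating
and estimated cycle coincide; at 5-year intervals the compounded matrix is
not the annual one and per-cell annualization of it is biased (see the
embedding remark above), which is a property of the estimator, not a bug in
the generator.

## Validation against empiric follow-up

The projection at the follow-up horizon (5 years) is compared with the
observed follow-up proportion using an exact Clopper–Pearson binomial
interval (beta-quantile inversion); the model is "consistent" when the
projected prevalence lies inside the interval. Exactness is preferred to a
Wald interval because validation proportions are small (~3%) and stratum
denominators are in the hundreds. Where a source reports only proportions
without denominators, the comparison uses reconstructed counts at plausible
stratum sizes and is a consistency check, not a reproduction of any
published interval.

## Numerical conventions and degenerate inputs

- Transition matrices must be row-stochastic to 1e-9; distributions sum to
  1 to 1e-9; estimated matrices row-sum to 1 to 1e-12 by construction.
- Empty panels yield a zero count table with a warning; origin states with
  zero person-years yield zero rates with a warning; events without
  person-time are an error (inconsistent table).
- The annualization formula rejects negative rates and non-positive
  durations; probabilities are computed with `expm1` for accuracy at small
  rates.
- Mixed-sex panels are rejected — strata are modelled separately
  throughout.

## Problem sizes

Default test and analysis scales: projections over 15–400 cycles (trivial
cost); microsimulation 10,000 × 200 replicates for intervals and a single
100,000-individual replicate for oracle agreement; parameter recovery at
n ∈ {500, 5,000, 50,000}; interval coverage with 200 sets of 40 replicates
of 400 individuals. These sizes give Monte-Carlo error comfortably inside
the tolerances they are tested against.

## Known limitations

- Time-homogeneity: one annual matrix for all ages, though transition
  rates plausibly rise with age and MetS resolution falls.
- No mortality: everyone survives every cycle, slightly overstating
  cumulative MetS development, more so in men.
- Baseline-state person-time attribution ignores mid-interval moves.
- The 2-component state pools heterogeneous pairs.
- No covariates (smoking, alcohol, medication classes beyond BP/glucose).
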