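# Methods

This note documents the statistical procedure implemented in `habsuit`,
its assumptions, its tunable parameters, and the design choices made
where the procedure was genuinely open.

## Preference curves

Continuous variables are modelled by a nonsymmetric trapezoid
SI(x; a₁..a₄): 0 outside [a₁, a₄], linear limbs, plateau 1 on [a₂, a₃].
The trapezoid is a deliberate simplification of a bell-shaped response
that still allows asymmetry (skewing away from, e.g., pollution
extremes). Fitting uses only *derivative statistics of presence values*:
per bootstrap resample (with replacement, at the original sample size)
a₁ = min, a₄ = max, a₂ = 25th percentile, a₃ = 75th percentile; the
summary curve takes per-parameter medians across replicates. Using the
observed extremes for a₁/a₄ targets the fundamental rather than the
realized niche — it widens the envelope and therefore the reported
uncertainty, which is the intended behaviour. The quartile optimum is a
robustness/width trade-off: lower percentiles are less robust across
bootstraps, higher ones describe too narrow an optimum.

Numerical conventions, pinned so tests can be exact:

* Percentiles use linear interpolation between order statistics
  (`numpy.percentile` default).
* Presence values are sorted before resampling, making the fit invariant
  to input permutation at fixed seed.
* An all-constant sample yields the degenerate curve a₁=a₂=a₃=a₄ with a
  warning; evaluation treats the shared point as plateau (SI = 1), the
  limit of a shrinking trapezoid. Generally the plateau wins wherever a
  degenerate limb makes the piecewise definition ambiguous.
* Bootstraps default to n_boot = 200. `bootstrap_convergence` reports the
  running-median trajectory per parameter and flags convergence when the
  trajectory's spread over the final 25% of replicates, relative to the
  final median, is below 10⁻³; it is advisory, not a stopping rule.

Categorical and binary variables get SI(class) =
(share of class among presences) / (share of class in all data),
normalised within each bootstrap by the maximal ratio; the summary is the
per-class median, renormalised to max 1. Classes never seen with the
species present score exactly 0 — no smoothing by default (a
`pseudo_count` option exists but is off), because the share-ratio formula
yields 0 and the bootstrap median of a rare class is near 0 anyway.
Binary variables are two-class categorical curves.

## Aggregation and classification

HSI is the geometric mean of the model's SIs, computed through logarithms
with an explicit zero short-circuit (no underflow at large m, exact 0
whenever any SI is 0). This encodes niche interference: unsuitable
conditions in one factor cannot be compensated by others. Variables with
missing input at a site are dropped and m reduced, so partially observed
sites still receive an HSI; a site observing none of the model's
variables is reported as unevaluable, not as 0. Presence is predicted
when HSI ≥ threshold, ties classified as presence.

## Training sets

Training sets are prevalence-balanced: n_each presences and n_each
backgrounds (default 25 + 25), both bootstrap sampled with replacement.
Balance at 0.5 removes the prevalence dependence of threshold-based
objectives. Background records are *sites where no presence was
recorded*, not confirmed absences. Their selection probability decays
with the Euclidean distance d to the nearest presence as exp(−d/λ); the
decay form is a package choice (the qualitative requirement is only that
the chance decreases with distance), with λ defaulting to the median
nearest-presence distance of the background pool — scale-free and
data-driven. λ = ∞ gives uniform selection. Distances are planar metres;
no CRS handling. The nearest-presence distance is computed once against
the full presence pool, since weighting applies to the pool before
sampling. An optional juvenile filter keeps presence records with
individual length strictly below 15 cm (the conventional adult split for
stream salmonids); backgrounds, which carry no length, pass through, and
presence records lacking a length are dropped.

## Evaluation

From the confusion matrix (A TP, B FP, C FN, D TN): CCI = (A+D)/N,
Sn = A/(A+C), Sp = D/(B+D), TSS = Sn+Sp−1, and Cohen's kappa
(Po−Pe)/(1−Pe) with Pe = [(A+B)(A+C)+(C+D)(D+B)]/N². Metrics with an
empty marginal are NaN, never silently 0. AUC uses the tie-corrected
rank (Mann–Whitney) form — exactly the all-pairs concordance
probability, testable to machine precision against brute force. The
TSS-optimal threshold scans the grid {0, 0.01, …, 1} and returns the
smallest maximiser. Qualitative gradings: kappa > 0.6 well-performing;
AUC bands [0.5, 0.7) poor, [0.7, 0.9) reasonable, ≥ 0.9 very good
(interval edges assigned upward). All reported metrics are training-set
metrics and are labelled as such; no held-out validation scheme is
implemented.

## Variable selection

A simple GA over inclusion bit-strings: population 50, up to 100
generations, tournament selection (size 3), uniform crossover at rate
0.7, per-bit mutation 1/L, elitism 1, early stop after 25 stagnant
generations. Fitness is the max-over-threshold TSS of the flagged model
on the training set; the empty chromosome carries sentinel −1 and is
repaired by flipping a random bit. Ties in fitness break toward fewer
variables (parsimony reduces overfitting risk), then lexicographic bit
order, making results deterministic at fixed seed. Curve parameters are
frozen during the search — the GA selects variables, not parameter
values; parameter uncertainty enters only through the bootstrap
replicates of the curves. Fitness is memoised per bit pattern, so on
small rosters the GA visits each subset at most once and
`exhaustive_search` (full enumeration, L ≤ 20) provides a cheap oracle.

## Ensemble and scenarios

`build_ensemble` repeats draw-training-set → GA with per-member child
seeds split from a master seed via `numpy.random.SeedSequence.spawn`
(members independent, ensembles exactly reproducible). Members failing
on a degenerate draw are re-drawn with a fresh child seed (bounded
retries). All members share the summary curve parameters fitted once
upstream. Support(v) is the inclusion fraction; its uncertainty is the
binary Shannon entropy in bits, the only normalisation under which 50%
inclusion gives uncertainty exactly 1.

Scenario coupling joins an abiotic base table to the nearest biotic
record within 100 m (Euclidean; a pair at exactly the radius is kept,
"exceeding" it excluded). Each site is collapsed to one state per
variable: continuous → median; categorical → median of the class codes
in declared order, and when that falls between two classes the *worst
case* wins — the tied class with the lower fitted SI, or the later
declared class if the SIs tie too. Per site the ensemble reports the
mean and standard deviation of HSI over the members able to evaluate it
(members with no observed variable at the site are excluded, and the
used count is reported) and the minimum SI per variable over members
including that variable — blank when no input data exist. Site counts
above/below decision thresholds default to {0.2, 0.6, 0.8}
(over-estimating, central, and under-estimating scenarios).

## Synthetic data

The generator emulates a riverine monitoring dataset: uniform planar
coordinates over a 10 × 10 km extent, environmental values uniform over
each variable's support (optionally beta-skewed or class-weighted), and
occurrence driven by a known niche — trapezoids and class-SI tables whose
geometric mean is the *true* HSI. The default study conditions are 166
presence records of which 25 are completely observed (missingness rate
0.5 per variable outside a protected complete subset, injected per
status stratum so the 25-complete count is exact while remaining
label-independent within strata), 600 background records, and a roster of
eight candidate variables — four informative (water temperature 6–10–16–20
°C, stream velocity 0.2–0.5–1.0–1.5 m/s, substrate preference
gravel > cobble > boulder > fine, pool presence) and four pure-noise
(depth, width, algae, conductivity). Occurrence defaults to the
deterministic rule presence ⟺ true HSI ≥ 0.6, which makes recovery
properties assertable record-by-record; a Bernoulli(true HSI) rule is
available for stochastic occurrence.

What the generator does *not* emulate: spatial autocorrelation of the
environment, dispersal limitation, biotic interactions, observation
error, and temporally varying conditions. Passing recovery tests
therefore show that the pipeline identifies a purely abiotic,
stationary niche from presence/background data of this size — not that
it would do so under the confounding present in real monitoring data.

## Problem sizes used in tests

The test and acceptance runs use the study-scale dataset (166 presences,
600 backgrounds) with ensembles of 50 members, genetic-algorithm
instances of 6 candidate variables checked against exhaustive search
over 20 training draws, trapezoid recovery at n = 1000 presences with
200 bootstraps, and 10 000-fold property sweeps for the metric and
geometric-mean identities — sizes at which every stochastic check has
comfortable margin while the whole suite runs in minutes on one CPU.

## Known limitations

* The distance-weighting form (exponential) and scale are conventions;
  ensemble support spreads depend on them and should be read with the
  weighting function as metadata.
* Per-member re-fitting of curve parameters from bootstrap replicates is
  not implemented; ensemble spread reflects training-draw and search
  stochasticity only.
* Date-based coupling is spatial-plus-exact-day only; no temporal
  tolerance window.
* No cross-validation or held-out evaluation; metrics are training-set
  values.
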