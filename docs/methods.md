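# Methods

## Data model and risk sets

A left-truncated right-censored (LTRC) sample holds, per subject, an entry
time t ≥ 0, a follow-up time y = min(x, c) with y > t, an event indicator
δ = 1{x ≤ c}, and a covariate vector z ∈ ℝᵖ (p = 0 for univariate work).
Observation is conditional on t ≤ y; the `apply_observation_filter`
operation realizes exactly that criterion on latent (T, X, C) triples.
Two risk-set predicates are used deliberately side by side:

* **closed**, R(y) = {j : tⱼ ≤ y ≤ yⱼ} — the product-limit, Cox and
  Breslow machinery;
* **right-open**, R(y+) = {l : tₗ ≤ y < yₗ} — the monotone estimator's
  interval weights, because a subject contributes time at risk on
  [vᵢ, vᵢ₊₁) only while its follow-up extends beyond vᵢ.

Edge conventions worth stating plainly:

* A record with y == t (zero-length observation window) is rejected with
  a validation error, never silently dropped — such a subject carries no
  information, and silent dropping hides data problems. The observation
  filter therefore raises on the measure-zero tie T == Y rather than
  keeping a degenerate record.
* Knot uniqueness is exact floating-point equality; no tolerance merging.
  Simulated continuous times are almost surely distinct, and merging would
  silently change the failure counts d(·).
* A censored record tied with a failure stays in the closed risk set at
  that time (t ≤ y ≤ yⱼ holds).
* Covariates are used as given; no internal centering (centering would
  silently change the reference level of the baseline hazard).

## Cox fitting

`cox_fit` maximizes the delayed-entry partial likelihood by
Newton–Raphson from β = 0, with step-halving (up to 20 halvings when a
step does not improve the log-likelihood), convergence at max-norm of the
score ≤ 1e-8, at most 50 iterations. Ties share a Breslow denominator;
the Efron correction is out of scope. Risk-set sums are computed in
O(n log n) per iteration by two cumulative sums (over entry-sorted and
follow-up-sorted orders). A coefficient exceeding 15 in absolute value
trips a monotone-likelihood flag: e¹⁵-scale relative weights make every
downstream weight meaningless, so the fit is flagged rather than silently
returned. A constant covariate column raises immediately (singular
information).

## The monotone baseline MLE

On the merged grid v₁ < … < v_k of all entry and follow-up times, the
conditional log-likelihood of a nondecreasing step baseline hazard is

    ℓ*(λ₀) = Σᵢ dᵢ log λ₀(vᵢ) − wᵢ λ₀(vᵢ),
    wᵢ = (vᵢ₊₁ − vᵢ) Σₗ exp(β̂᝘zₗ) 1{tₗ ≤ vᵢ < yₗ},

maximized subject to monotonicity by weighted isotonic regression
(`scipy.optimize.isotonic_regression`, the linear-time stack PAVA). Three
independent routes to the same solution are kept for verification: the
brute-force O(k³) max–min window enumeration and the greatest-convex-
minorant left derivatives of the cumulative-sum diagram, both exercised
against the PAVA in the test suite on random instances.

**Zero-weight intervals.** An interval can have wᵢ = 0 (nobody at risk
over it). If additionally dᵢ = 0 it imposes no constraint and takes the
fitted value of the next constraint-bearing interval. The case
wᵢ = 0 < dᵢ *does occur* — a subject failing at vᵢ leaves the right-open
risk set at its own failure time, so an isolated early entrant failing
before anyone else has entered contributes a failure with no time at
risk. Its likelihood term dᵢ log λᵢ is unpenalized, and the constrained
maximizer pools it forward into the next block; this is implemented as a
generalized ratio-PAVA (isotonic Poisson regression with blocks
(ΣD, ΣW), a W = 0 < D block having value +∞) and agrees exactly with the
max–min formula under the convention that zero-total-weight windows are
skipped. A trailing such block cannot arise from real data: the
longest-observed subject always keeps the final interval's weight
positive.

**Boundaries.** The hazard is 0 before v₁; beyond v_k it extends at the
last fitted rate, covering both a censored and a failed largest
observation (a failure at the final knot lies outside every max–min
window, so it is counted in d but cannot raise any rate — the single-
record sample therefore has λ̂ ≡ 0). The cumulative hazard is the exact
integral of the step function: continuous, piecewise linear, 0 at 0;
survival Ŝ(y|z) = exp(−Λ̂₀(y) e^{β̂᝘z}) is continuous and nonincreasing.

**Two-stage construction.** β̂ is estimated once by `cox_fit` and passed
in; the monotone module never re-estimates it. `tsai_estimator` is the
empty-β special case, `lopuhaa_estimator` re-fits on a copy with all
entries zeroed (the comparator is defined for right-censored data only;
on truncated data its risk sets are inflated supersets, and its survival
estimates sit systematically above the truncation-aware ones).

## Simulation design

The study battery emulates a two-group cohort: gender Z ∈ {0, 1}, initial
n/2 males and n/2 females; event and censoring times i.i.d.
Weibull(a, θ_Z) within gender with θ₀ = 1000 (males) and θ₁ = 2000
(females) — exchangeability of X and C makes the observed censoring rate
50% exactly, up to Monte-Carlo noise — and truncation T ~ Weibull(a, b)
with the shared shape a. Weibull is parameterized in scale form (density
∝ (a/θ)(x/θ)^{a−1} e^{−(x/θ)^a}); only this reading makes the group
medians m_Z = (log 2)^{1/a} θ_Z come out at 693/833/912/941 (males) and
double that for females. Proportional hazards holds exactly with true
coefficient β = a·log(1/2). The four (a, b) settings are (1, 50),
(2, 250), (4, 500), (6, 600); b is chosen so the observed subgroup sizes
are comparable across shapes (e.g. at a = 1 the male inclusion
probability has the closed form (1/50)/(1/50 + 1/500) = 10/11).

Per scenario, each estimator is scored by Ŝ(m_Z | Z=z) against the true
value 0.5: average bias, empirical standard error (SD across replicates,
ddof = 1), and mean squared error (so mse = bias² + ese²·(R−1)/R exactly).
Subgroup estimators (truncated KM, Tsai) are fit on the Z = z subset
only; covariate estimators share one truncation-adjusted β̂ per
replicate. Degenerate replicates (empty subgroup, non-converged or
monotone-likelihood-flagged Cox fit) contribute a missing value and a
tally — re-drawing would bias the Monte-Carlo distribution. A subgroup
with no failures is not degenerate: its product-limit curve is
identically 1 and is recorded as such.

Per-replicate generators are spawned from the root seed via
`numpy.random.SeedSequence.spawn`, making every replicate independent and
individually reproducible; identical seeds give bit-identical results.

**Extreme early-truncation design.** T ~ Weibull(4, 3000) for both
genders, so only ≈0.6% of males and ≈9% of females pass the observation
filter. Latent pools of 100 000 are drawn and filtered until the eligible
records contain at least one rare early entrant (T < 200) and at least
1000 records in total (one pool almost always suffices); all early
entrants are retained and the rest of the 1000 is sampled uniformly
without replacement. The resulting sample holds only ~64 males, observed
under heavy truncation — the stress test for discrete-hazard estimators.
A cap of 100 pool regenerations converts a pathological parameterization
into a diagnosable error.

A known discrepancy is documented here deliberately: with this design the
truncated KM estimator is near-unbiased at the male median in our runs,
and the monotone estimators carry the mild upward small-sample bias also
seen in the n = 100 battery. Published results for comparable extreme
settings report large *downward* biases for all truncation-adjusted
estimators, consistent with every observed exit being scored as an event
(the non-monotone discrete estimator then tracks the distribution of
min(X, C), whose survival at the male median is exactly 0.25). This
package keeps the censoring indicator intact; the acceptance suite's
extreme-scenario expectations are asserted as published and the
difference is left visible rather than reproduced by dropping the
indicator.

## What the generator does and does not emulate

The synthetic design gives exact proportional hazards, a single binary
covariate, independent (T, C) and X, and continuous tie-free times.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions — they say nothing about misspecified
hazards (non-monotone, crossing), covariate-dependent truncation, tied or
interval-censored real-world times, or high-dimensional covariates.
Nonincreasing-hazard variants, confidence bands (the cube-root-rate
Chernoff limit), and post-hoc smoothing of the step hazard are out of
scope.

## Numerical choices

* Weighted isotonic regression delegates to scipy's PAVA when all weights
  are positive; the generalized ratio-PAVA handles zero weights.
* At-risk masses on the grid are accumulated by a difference-array
  cumulative sum in O(n + k); cancellation residues below 1e-9 of the
  largest subject weight are snapped to exactly zero so empty risk sets
  are empty, not 1e-13.
* Curve CSVs are written with 17 significant digits and read back with
  round-trip float parsing, so a written curve re-evaluates identically
  at its own grid points; table-reproduction CSVs round to 3 decimals.
* Problem sizes in the test suite: the n = 1000 batteries run at
  R = 1000 replicates, the extreme design at R = 150, Cox recovery at
  R = 200 — sizes chosen so the full suite completes in well under a
  minute of simulation time while keeping Monte-Carlo tolerances (3
  standard errors of a difference of means) meaningful.
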