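# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the simulation engine does and does not
emulate, and the places where the design space was genuinely open.

## Restricted inverse-moment priors

All alternative hypotheses use the inverse-moment density
π_I(θ; θ′, k, ν, τ) restricted to (θ′, 1).  The substitution
w = ((θ−θ′)²/τ)^(−k) maps the right half of π_I to a Gamma(ν/2k, 1) law in
w, truncated to w ≥ ((1−θ′)²/τ)^(−k).  Every quantity the package needs is
therefore analytic through the regularized incomplete gamma function:

- normalizer P(θ′ < θ < 1) = ½·Q(ν/2k, w_min), reducing to
  ½·exp[−τ(1−θ′)⁻²] for the default k=1, ν=2;
- CDF and quantile function (hence exact inverse-CDF sampling — no
  rejection steps, reproducible to the draw);
- mode θ′ + (2kτ^k/(ν+1))^(1/2k), the formula used to calibrate τ: with
  ν=2, k=1, τ₁=0.06 puts the response-rate prior mode at 0.3 from a 0.1
  null, and τ₂=0.015 puts the difference prior mode at 0.1.  A τ large
  enough to push the mode past 1 triggers a warning, since the restricted
  prior is then monotone on its support.

Defaults throughout: k=1, ν=2; θ = θ′ evaluates to density 0 (continuous
extension) so integrators never see the pole.

## Marginal likelihoods

A hypothesis is a contiguous partition of the doses into blocks sharing a
rate, each block carrying a point mass at θ₀, a restricted inverse-moment
prior anchored at θ₀ or at the previous block's rate, or a Uniform(0,1)
prior (model-averaging models).  This one structure expresses the two-dose
family {H0..H3}, the three-dose family {H0..H7}, the model-averaging
families {M1, M2} / {M1..M4}, and the single-arm pair used by the
independent comparator.

The default integrator is deterministic nested Gauss–Legendre quadrature
(128 nodes per free dimension) after an inverse-CDF change of variables
per inverse-moment block: the prior becomes the uniform measure on (0,1),
which absorbs the near-singular density peak exactly, and a Uniform block
integrates polynomials of degree ≤ 255 exactly.  Relative accuracy at the
default node count is ~10⁻⁶ (refinable by raising `nodes`), far below any
decision threshold's sensitivity.  Because the node tensors are
data-independent they are tabulated once per hypothesis, so one marginal
evaluation is a handful of vectorized power operations (~1 ms for the
two-dimensional H3).  Monte Carlo integration over prior draws is retained
as a verification mode and reports its standard error; the test suite
checks the two routes against each other across the data lattice.
Marginal likelihoods include the binomial coefficients (they cancel in
posteriors but keep values comparable with the closed beta form of the
pooled-uniform model, C(n₁,x₁)C(n₂,x₂)·B(Σx+1, Σ(n−x)+1)).

Interim decisions depend on the data only through the per-dose sufficient
statistics, so marginals are cached on (x, n); replaying identical
replicates performs no new quadrature.  Under continuous monitoring with
Bernoulli randomization most stopped trials stop at their first look,
whose states rarely repeat exactly, so measured hit rates across a
1,000-replicate run are ~60% — the cache still removes the majority of
evaluations, and a miss costs under a millisecond.

For the ordered model M2 (θ₁ ~ Uniform, θ₂ | θ₁ ~ π_rI anchored at θ₁) the
conditional prior is normalized per θ₁, the generative reading of the
model; the posterior on the ordered triangle is evaluated on a fixed
2,000×2,000 midpoint grid built in log space, because the conditional
normalizer underflows as θ₁ → 1 even though the density ratio stays
finite.  Tail-probability accuracy against independent grids is ~10⁻³.

## Monitoring semantics

Decisions follow the printed rules with strict inequalities everywhere:

- **BHT** (full): after a 24-patient total burn-in, stop at the first look
  where p(H₀|x), p(H₁|x) or p(H₂⋆|x) exceeds Pₐ = 0.65; at the 54-patient
  maximum the same thresholds are applied once more and the trial is
  otherwise inconclusive (the only reading consistent with nonzero
  inconclusive rates).  An H₂⋆ stop refines to H₂ iff
  p(x|H₂)/p(x|H₃) > P_b = 1.2 (a vanishing H₃ marginal counts as equality).
  BHT-A places prior mass ¼ on each hypothesis; BHT-B places ⅓ on H₀, H₁
  and H₂⋆ with H₂⋆ split evenly, and uses the same P_b refinement.
- **BHT futility-only** (for comparison with designs lacking efficacy
  stopping): terminate when p(H₀|x) > 0.848; close the lower arm when
  p(H₁|x) > 0.848 (subsequent patients go to the high dose; the posterior
  keeps updating with the frozen lower-arm data, so a later H₀ stop
  remains possible); each arm enrolls to 45; end-of-trial claims need
  posterior > 0.5, with the H₂/H₃ ratio cutoff 1.37.
- **BMA**: stop when p₁ > P_e = 0.7 (H₂ iff posterior model odds > P_g =
  1.3, else H₃) or p₂+p₃ > P_f = 0.65 (H₀ iff p₂−p₃ ≤ P_k = 0.02, else
  H₁); p₁ is checked first when both fire (order of statement).
- **Toxicity**: monitored from the first patient.  Per-dose beta priors
  (defaults Beta(0.5, 16.5) / Beta(0.5, 8.5), the phase-I borrowing below)
  give independent posteriors; 10,000 joint draws per state are passed
  through the precision-weighted isotonic projection, and dose i is toxic
  when P(p⋆ᵢ > 0.3 | data) > P_c = 0.8.  All doses toxic terminates the
  trial; a toxic top segment closes those arms.  The draw count keeps the
  exceedance standard error below 0.005 near P_c; each toxicity state is
  evaluated once on a substream derived from the state and an `mc_seed`,
  making the decision a fixed deterministic function of the data (the same
  discipline applies to the BIT design's posterior summaries).
- **Comparators**: the independent design tests each arm separately
  (thresholds Pₐ⋆ = 0.7, per-arm burn-in 12, cap 27) and splits H₂⋆ by
  P(θ₂−θ₁ > 0.1 | x) ≤ P_d = 0.11 computed deterministically from the
  per-arm nonlocal posteriors on a 4,000-point grid (a flat-prior variant
  is a config switch).  BIT uses Uniform priors, projected beta-posterior
  draws, thresholds P_h = P_i = 0.65, P_j = 0.4, and defines
  p(θ₁=θ₂ | data) as the fraction of draws the projection pools — the only
  event with positive probability of exact equality.  The Simon two-stage
  design is found by exhaustive enumeration (n ≤ 100) with exact binomial
  error rates, minimizing expected null sample size (ties: smaller n, then
  smaller n₁); stage 2 is not curtailed.

After a toxicity closure of the high arm, the published design rules are
silent on how efficacy concludes; here they continue as a single-arm
evaluation of the low dose (same priors), mapping a promising low dose to
H₂ and a null one to H₀.  In the studied scenarios (toxicity 0.15 with the
informative priors) no closures occur, so this choice does not move any
reported number.

### Phase-I borrowing for the toxicity priors

Starting from Beta(0.5, 0.5), every three toxicity-free patients one level
above a phase II dose count as five toxicity-free patients at it, applied
per level of separation with each level's converted pseudo-count rounded
to a whole patient (3·(5/3)² = 8.33 → 8).  Four phase-I levels with three
toxicity-free patients each and the phase II doses at the middle levels
give Beta(0.5, 16.5) and Beta(0.5, 8.5).

## The simulation engine

Patients arrive one at a time, are randomized i.i.d. with probability ½
among the open arms (so per-arm counts vary across replicates), and their
binary response and toxicity are drawn independently from the scenario's
true rates with outcomes available immediately — no accrual, assessment
lag, or dropout.  Toxicity is checked before efficacy at every patient.
One master seed spawns one substream per replicate, and within a replicate
separate streams drive assignment, response and toxicity, so designs can
be compared on common random numbers; Monte-Carlo decision functions use
the state-keyed `mc_seed` streams above.  Toxicity-terminated replicates
count in every denominator, including average sample size.

These simulations therefore show how the *decision rules* behave when
their assumptions hold exactly; they do not probe misspecified
monotonicity, delayed outcomes, or response/toxicity correlation.

## Problem sizes and tolerances

Reported operating characteristics use 1,000 replicates per (design,
scenario) cell, matching the tables the bundled `table1.yaml` /
`table2.yaml` grids reproduce; a cell runs in ~10–30 s on one CPU, the
full grids in about an hour.  Unit tests reduce only what is incidental to
the property under test (e.g. the model-averaging recovery check uses 50
replicates and a 600-point grid).  Simulation frequencies are compared at
three binomial standard errors; analytic quantities at 10⁻⁸ relative or
tighter; the isotonic projection against an exact constrained-QP oracle at
10⁻¹⁰.

## Known limitations

- Three-dose support is structural (hypothesis/model families, marginals,
  posteriors); the monitoring front-ends and simulator target the two-dose
  trial, and no published three-dose numbers exist to validate against.
- Between-look dependence of the monitored posteriors is handled only by
  threshold calibration (as designed), not by any error-spending scheme.
- The exact-integration engine reproduces the published
  operating-characteristic tables within Monte-Carlo tolerance with one
  borderline cell: the null-scenario P(H₀) of the monitored joint design
  concentrates near 0.914 here against a printed 0.936 (itself a
  1,000-replicate estimate with standard error 0.008), while every other
  cell — including the null scenario's other rows — agrees.  Balanced
  block allocation and noise in the interim integrations were both tested
  as explanations and change nothing.
- Adaptive randomization and umbrella (non-monotone) orderings are out of
  scope by design.
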