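# Methods

## Elicitation model and beta fitting

Each expert's belief about a cure probability is recorded as five points of
their subjective CDF: plausible minimum, lower quartile, median, upper
quartile, plausible maximum.  The plausible extremes are "extremely
unlikely but not impossible" values; they are assigned cumulative
probabilities 0.01 and 0.99 (configurable through `QuantileJudgement` /
`CohortConfig.probs`), the convention common in SHELF-style practice, with
the quartiles and median at 0.25/0.5/0.75.

A `Beta(α, β)` is fitted by minimising `Σₖ (F(vₖ; α, β) − pₖ)²`, the sum of
squared differences between fitted and elicited cumulative probabilities,
with equal weights on the five points (no weighting scheme is standard, and
none is claimed).  The search is Nelder–Mead in `(log α, log β)` — the log
parameterisation enforces positivity without constraints — started from a
moment-matched point (median ≈ mean, IQR/1.349 ≈ sd, inverted to beta
parameters and clipped into `[1e-2, 1e4]`).  The simplex is restarted once
from its own optimum, and if the objective is still above 1e-10 a few fixed
fallback starts are tried and the best kept; this removes the rare stall
without ever consulting the ground truth.  Convergence tolerance is 1e-10
on the objective with at most 2000 iterations per start (both
configurable); an optimiser failure sets `converged=False` rather than
raising.  A judgement whose whole plausible range is narrower than 0.02
(an extremely confident expert) triggers a warning but is still fitted.
Five exact beta quantiles determine the two parameters essentially
uniquely; in practice recovery over α, β ∈ [0.5, 50] is far inside the 5%
relative-error budget the tests assert.

## Joint belief density

With θ₂ = θ₁ + (1 − θ₁)θ₃ and independent beta marginals for (θ₁, θ₃), the
joint density of (θ₁, θ₂) is the product of the two beta densities times
the Jacobian 1/(1 − θ₁), supported on 0 ≤ θ₁ ≤ θ₂ ≤ 1.  Evaluation is in
log space (two beta log-pdfs plus `−log1p(−θ₁)`) and exponentiated at the
end, so hyperparameters in the hundreds of thousands (used to build
near-point-mass checks) do not overflow.  Conventions at degenerate points:

- θ₁ = 1 (a measure-zero line where the ratio terms are 0/0): density 0.
- θ₂ = θ₁ with α′ < 1: the density genuinely diverges; the limit is
  returned as `inf` and the plotting grid, being cell-centred, never hits
  it.

Surfaces for contouring are evaluated on a cell-centred lattice over
[0, 1]², default resolution 200 (100 in the pipeline, where 24 surfaces are
written); the lattice Riemann sum of a smooth surface is within ~2% of 1 at
resolution 400, and adaptive quadrature of the density over the triangle
reproduces 1 to 1e-3 — both asserted in tests.  Joint sampling draws θ₁ and
θ₃ from their betas and maps through the reparameterisation: exact draws,
no MCMC error.

## Posterior updating and the odds-ratio sweep

The original analysis ran Gibbs sampling (three chains, 30,000 total
iterations, Gelman–Rubin checks).  The model is conjugate and the posterior
factorises, so this package samples the exact posterior betas directly; the
convergence diagnostic is unnecessary and dropped, and the conjugate update
is validated against a brute-force grid posterior (prior × likelihood on a
fine grid, renormalised, moment-matched to 1e-6).  The Monte-Carlo size for
the odds-ratio posterior stays at 30,000 draws by default.

Odds-ratio draws clamp θ values into `[1e-12, 1 − 1e-12]` before forming
odds, so a machine-boundary draw cannot divide by zero.  Credible intervals
are equal-tailed (2.5%, 97.5%) — reproducible and standard; highest-density
intervals are out of scope.  Because θ₂ ≥ θ₁ by construction, every OR draw
is ≥ 1 (up to the clamp); "convinced" therefore means the upper limit falls
strictly below the threshold, with OR = 1.5 as the default
clinically-worthwhile bound.

The trial-size sweep always prepends size 0, the prior-only analysis, and
reports sizes both per-arm and doubled ("trial size" is quoted in both
conventions in the literature).  Per-(size, expert) seeds are spawned from
the master seed via `SeedSequence` and recorded in the output table, so any
single row can be reproduced in isolation.

## Synthetic cohort: what it emulates and what it does not

The generator emulates a cohort of 24 experts in 5 practices (sizes
4, 5, 5, 5, 5) spanning three archetypes defined by their θ₃ beliefs:

- confident-optimist: base truth θ₁ ~ Beta(15, 10), θ₃ ~ Beta(8, 20)
  (θ₃ median ≈ 0.28 ≥ 0.20, sd ≈ 0.084 < 0.10);
- confident-pessimist: θ₁ ~ Beta(18, 9), θ₃ ~ Beta(1.2, 30)
  (θ₃ median ≈ 0.029 ≤ 0.05, sd ≈ 0.034 < 0.10);
- uncertain: θ₁ ~ Beta(3, 3), θ₃ ~ Beta(2, 4) (θ₃ sd ≈ 0.18 > 0.15).

The per-practice mix mirrors the reported pattern: one practice uniformly
optimistic about the adjunct, one uniformly pessimistic, one predominantly
pessimistic, two diverse.  Within an archetype, each expert's personal
ground truth multiplies the base parameters by log-normal factors
(σ = 0.15), re-drawn until the archetype's defining θ₃ constraints still
hold — jitter creates within-archetype variation but cannot move an expert
out of their archetype.  Elicited quantiles are the exact beta quantiles of
the personal truth; optional rounding to whole cows out of 100 (experts
answered in those terms) is off by default so recovery tests are exact, and
when on, ties are repaired to keep quantiles strictly increasing inside
(0, 1).  `P(θ₂ < θ₁)` is 0 with probability 15/24 and otherwise uniform on
(0, 0.05), matching the reported split.

For the null-effect trial the treatment-1 cure count is not stated anywhere
in the source material; the default is `assumed_theta1 = 0.5` with
deterministic `x1 = round(n1·θ1)` (binomial draws available), the maximally
non-informative midpoint.

What the generator does **not** emulate: interview dynamics (anchoring,
tail underweighting, feedback revision), correlation between an expert's θ₁
and θ₃ beliefs beyond the archetype structure, or covariate effects
(qualifications, experience) on beliefs.  A green sweep test therefore
establishes that the machinery behaves correctly on a cohort with the
stated structure — not that the original cohort's specific numbers (its
prior intervals, or "23 of 24 convinced at 500/arm") are reproduced; those
depend on the unpublished elicited priors.  The synthetic pessimists are
idealised (tightly concentrated near θ₃ = 0), so more synthetic experts are
convinced a priori than was observed in the field.

## Classical scaling

Dissimilarity is squared Euclidean distance between 10-vectors of elicited
values.  The scaling double-centres −D/2, eigendecomposes with `eigh`,
orders eigenvalues descending (stable sort; ties keep decomposition order),
and returns coordinates `v√λ` for eigenvalues above a relative tolerance of
`max(n, 10)·eps·max(λ)`.  Negative eigenvalues can only be floating-point
noise here (the input is genuinely squared-Euclidean) and are truncated to
zero.  Goodness of fit divides by the sum of the first 10 eigenvalues —
the dimensionality of the raw vectors — so gof reaches exactly 1 at m = 10.
Axis signs are fixed by making each eigenvector's largest-magnitude entry
positive, for reproducible maps.  A constant configuration (all eigenvalues
at noise level) raises rather than returning an empty map.

Axis interpretation: for squared-Euclidean input, classical scaling equals
principal components of the centred data matrix, so the loading of elicited
position p on axis k is the unit right-singular-vector entry
`Xcᵀ uₖ / √λₖ`.  Loadings need the raw vectors and are attached only by
`scale_vectors`; `classical_scale` alone (distances only) leaves them
unset.  On the default synthetic cohort the dominant axis loads mainly on
the five θ₃ positions, as the archetypes differ mostly there.

## Sampling design

The systematic PPS rule accumulates the *unrounded* interval from the
random start and floors each selection point only for the range lookup
(the worked trace 9 → 24.4 → floored 24 fixes the flooring, not the
accumulation; unrounded accumulation is the convention that preserves the
equal-probability property in general).  The interval must strictly exceed
the largest cluster or selection raises — the documented without-replacement
condition.  Within-cluster selection is uniform without replacement, taking
whole clusters smaller than the quota.  Under a uniform random start each
assigned integer is hit with probability exactly k/total, so when no
cluster is exhausted every individual's inclusion probability is
k_clusters·k_within/total; the test suite verifies this empirically at 10⁴
replicates.

## Pipeline and reproducibility

`run_full_analysis` derives all stage seeds from one master seed through
`SeedSequence`, writes every table as delimited text with a header line
naming the seed, the SHA-256 configuration digest and the package version,
and records the full configuration, derived seeds, convinced counts and any
per-expert fit failures in `manifest.json`.  Re-running the same
configuration reproduces every number bit-for-bit.  Failed expert fits are
excluded from downstream stages and listed in the manifest — reported,
never silently dropped.

Plot rendering (contour maps, scree plots, labelled 2-D maps) is left to
the user: every figure is one matplotlib call away from the exported grids,
eigenvalue tables and coordinates, and keeping the package free of a
plotting dependency keeps the analysis surface small.

## Known limitations

- Only the beta family is supported for priors; robustness to alternative
  families (normal, gamma) breaks conjugacy and is explicitly out of scope.
- Dependence between θ₁ and θ₃ is not modelled — the reparameterisation
  exists precisely to justify independence.
- The convinced count is a description of predicted beliefs under rational
  updating, not a decision analysis; utilities and costs are not modelled.
- Survey design effects (clustering variance, weighting) are not estimated;
  the sampling module reproduces the selection mechanism only.
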