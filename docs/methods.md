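# Methods

## Outcomes, data model, and scope

The package analyses two correlated binary outcomes per woman — attendance
of the recommended four or more antenatal-care visits (ANC) and delivery at
a health facility (DC) — observed across administrative zones and repeated
survey rounds. A `Dataset` is a validated rectangular table: the two 0/1
outcomes, a zone id, a survey-year label, a positive sampling weight
(defaulting to 1), and declared categorical covariates whose first label is
always the regression reference level. Spatial structure is a symmetric 0/1
zone-adjacency matrix with a zero diagonal, supplied as a plain edge list;
no polygon geometry is read, and all point operations assume projected
planar coordinates with Euclidean distances.

## Descriptive layer

The 2×2 joint table of the outcome pair is tabulated from (optionally
weighted) counts; cell probabilities, row/column marginals, the
cross-product odds ratio ψ = n11·n00/(n10·n01) and a Pearson chi-square test
of independence follow directly. Weighted tables use weighted counts in the
chi-square statistic with no design-effect (Rao–Scott) correction — a
deliberate simplification documented here because survey-design variance
estimation is out of scope. A zero off-diagonal cell makes the OR infinite;
callers can request the Haldane–Anscombe +0.5 correction instead.
Report percentages are rounded to 1 d.p. for display; full precision is kept
internally.

## The bivariate model

The contribution is a Plackett–Dale bivariate binary logistic regression.
Marginals are ordinary logistic regressions `p_k = logistic(x'β_k)`; the
joint distribution is completed by a *constant* dependency odds ratio ψ:
`p11` solves the Plackett quadratic `p11(1−p1−p2+p11) = ψ(p1−p11)(p2−p11)`
with the root inside the Fréchet interval `(max(0, p1+p2−1), min(p1, p2))`,
which is unique for every ψ > 0. Numerically the root is evaluated in its
conjugate form `2ψp1p2 / (s + √(s² − 4ψ(ψ−1)p1p2))` with
`s = 1 + (p1+p2)(ψ−1)`, which is free of the catastrophic cancellation the
direct quadratic formula suffers near ψ = 1 and returns `p1·p2` exactly at
ψ = 1; on the rare `s < 0` branch (tiny ψ with large marginals) the direct
form is the stable one and is used instead.

Each record contributes `w_i · log p_{gh}` for its observed cell — the
individual-level multinomial likelihood. Records are first collapsed to
unique (design-row, cell) patterns with summed weights, so likelihood
evaluation costs O(#patterns), not O(n). Maximization is quasi-Newton (BFGS)
over the stacked vector `(β₁, β₂, log ψ)` — or `(β₁, β₂)` when the
association is pinned — warm-started at the two univariate GLM fits with
`log ψ` initialized at the log of the empirical 2×2 OR (continuity-corrected
so a zero cell cannot produce an infinite start). Cells are clamped at
1e−12 before any log. The covariance of the estimates is the inverse
numerical Hessian of the negative log-likelihood at the optimum; when that
matrix is not positive definite the fit is returned with standard errors
flagged unavailable rather than silently wrong. Reported odds ratios are
`exp(estimate)` with 95% CIs `exp(estimate ± 1.96·SE)`.

Two useful exact identities, both enforced by tests: fixing `log ψ = 0`
factorizes the likelihood, so the joint MLE equals the two univariate MLEs;
and the intercept-only model on pure 2×2 data is saturated, so fitted cells
equal empirical proportions and the fitted ψ equals the empirical OR.

### Spatial term

Spatial dependence enters autologistically. For each outcome the observed
zone prevalence (weighted, computed per survey year by default — the
between-round time gaps are large enough that pooling would blur real
change; a flag pools them) is averaged over each zone's neighbors to give
`S_i`, and every record in the zone carries that value as a covariate. Each
outcome has its *own* autocovariate built from its own prevalence, giving
two coefficients ρ₁, ρ₂. `S_i` uses observed prevalences, not fitted values
— the classical "observed autocovariate" scheme — so it is a fixed covariate
during optimization. Island zones (no neighbors) fall back to the global
prevalence with a warning. Zones unobserved in a year are imputed at that
year's overall prevalence before neighbor-averaging.

Weights enter the likelihood as frequency weights (a pseudo-likelihood);
standard errors are model-based with no design correction, the same caveat
as the descriptive layer.

## Spatial statistics

**Moran's I** uses the textbook binary-weights form. Inference defaults to
the closed-form normal approximation under the randomization assumption
(the variance formula involving S0, S1, S2 and the sample kurtosis); that
variance has an (n−3) factor in its denominator, so the normal path requires
at least 4 connected zones. The alternative is Monte-Carlo permutation of
the values over zones with a fixed seed; the p-value is one-sided in the
direction of the observed deviation from E[I] = −1/(n−1), estimated as
(1+k)/(1+M). Island zones are excluded with a warning. The statistic is not
clamped to [−1, 1]: its true bounds depend on the weight matrix, and
checkerboard patterns on small lattices legitimately reach −1 exactly.

**Gi\*** is the standard Getis-Ord hotspot score with self-inclusion and
binary weights; zones are flagged hot/cold where the z-score crosses the
two-sided normal critical value at the chosen α. Constant input yields
all-zero scores with a warning (the variance term vanishes). One
non-obvious consequence of the standard formula, verified by direct
evaluation: an isolated single high zone is *not* its own top hotspot — a
neighbor with a smaller neighborhood can outscore it — which is why hotspot
claims should be about a zone *and* its surroundings, not a lone spike.

**Kriging.** The empirical semivariogram is the Matheron estimator on
equal-width lag bins up to half the maximum pairwise distance (default);
spherical, exponential and gaussian models are fitted by least squares
weighted by per-bin pair counts, with nonnegativity enforced by bounds and
the range capped at 3× the largest lag (beyond which the models are not
identifiable from the observed lags). Ordinary kriging solves the
semivariance system with the Lagrange unbiasedness constraint, so weights
sum to 1 at every target; with a zero nugget the interpolator is exact at
data locations with zero kriging variance. Exact-duplicate data locations
make the system singular and are rejected with advice to deduplicate (the
point reader already averages them).

## Synthetic survey generator

The generator is the package's test bed and emulates the study design the
package targets: a stratified multi-round survey of women clustered in
zones. Zones live on an r×c rook-adjacency lattice; zone effects per outcome
follow a SAR construction `u = σ(I − φW_row)⁻¹e` with iid standard-normal
`e` — chosen over ICAR/CAR because a single strength parameter φ ∈ [0,1)
with no sum-to-zero constraints is the simplest device that produces the
positive Moran's I the fitted autocovariate is meant to absorb. Covariates
are sampled from declared categorical distributions; outcome pairs are
drawn from the Plackett cells of `η_k = intercept_k + covariate effects +
year effect + u_k`.

Defaults are the study conditions: an 8×9 lattice (72 zones, close to
Ethiopia's zone count), 107 women per zone per round — ≈30,800 women over
four rounds, matching the pooled analytic sample — intercepts, year effects
(2016 reference) and wealth/residence coefficients at the published fitted
values, and dependency OR ψ = 2.029, the published conditional dependency.
φ = 0.6, σ = 0.5 were fixed once as a moderate clustering level: the source
analysis reports strongly significant clustering but no generative spatial
parameters, and these values give zone-prevalence Moran's I comfortably
above its null without degenerate all-or-nothing zones. An optional weight
generator attaches lognormal cluster-level weights (constant within
zone×year), the shape induced by two-stage cluster-proportional sampling.

Deliberate misspecification: the generator injects space through latent
zone effects while the fitted model absorbs it through the observed
autocovariate. That mirrors real autologistic practice, and it is why
recovery tests compare ρ against simulation behaviour rather than against
φ. What the generator does *not* emulate — and passing tests therefore do
not certify — includes nonresponse, informative missingness, real EDHS
strata/EA geography, and recall error.

## Problem sizes and numerical choices

The test suite and acceptance script run at deliberately chosen scales: the
printed-table reproductions are exact at their published n (~7,300–8,000
per round); the Plackett round-trip uses 1,000 random triples at tolerance
1e−8; permutation inference is checked against exhaustive enumeration on
≤6 zones (≤720 labelings) with 20,000 Monte-Carlo draws; and the
simulation-estimation study uses 50 replicates of ~20,000 women each
(9 zones × 2,222), with every estimate required to fall within 3 Monte-Carlo
standard errors of its generating value. Optimizer settings: BFGS with
gradient tolerance 1e−8; GLM warm starts run IRLS to tolerance 1e−12;
variogram fits use least-squares tolerances of 1e−14. All randomness flows
from explicit seeds; identical (config, seed) reproduce byte-identical
datasets and reports.

## Known limitations

- No survey-design variance estimation (jackknife/linearization) and no
  Rao–Scott corrections; weighted SEs are model-based.
- No random-effects (GLMM) variant; the spatial term is the fixed
  autocovariate only.
- The association is a single constant ψ; covariate-dependent association
  and non-Plackett copulas are out of scope.
- Great-circle distances, anisotropic variograms and universal/co-kriging
  are unsupported; coordinates must be projected.
- Local Moran (LISA) and map rendering are intentionally absent.
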