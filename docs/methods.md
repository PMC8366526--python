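# Methods

This note documents the statistical model behind `marshequiv`, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Paired standardization

Each of the 18 ecological metrics is reduced to one value per site
(plus, where applicable, a within-site SD over field replicates) and
standardized per pair as Z = (LS − NM)/σ_pooled. Two pooled-SD modes
exist because the sampling designs differ in comparability:

- **local** (soils, invertebrates, plants): identical replication at
  both members of a pair makes the within-site replicate SDs directly
  comparable, so σ_L = sqrt((σ²_LS + σ²_NM)/2) per pair.
- **regional** (nekton, herons, terrapin): mixed gears or unequal
  effort preclude a within-site SD, so one shared
  σ_R = sqrt((SD²_LS + SD²_NM)/2) per metric is built from the sample
  SDs of site-level values across pairs. Regional SDs always use
  site-level values (one per site), not raw replicates — the natural
  reading of "among-pair" spread. Nekton metrics are forced to the
  regional mode even when replicate SDs are computable.

Sample SDs use the n−1 denominator throughout. A degenerate (zero)
pooled SD excludes that metric for the affected pair (local) or the
whole metric (regional) with an explicit warning rather than emitting
±∞; net scores average over the scores that exist. The auxiliary
low-marsh-only mussel density is scored like any metric but excluded
from the net score, which therefore averages 18 metrics.

The overall mean ± SD is reported two ways — over all pair × metric
scores and over the 18 metric-level means — because the two SDs differ
even though the means coincide on complete data; both are exposed on
`EquivalenceTable`.

### Aggregation rules

- **Soils**: each core's 0–5, 5–10, 10–20 cm sections are combined by
  thickness weights (5, 5, 10)/20. Bulk-density-mass weighting would be
  defensible but requires data the pipeline does not carry; thickness
  weighting is the default and only implemented variant.
- **Bivalves**: mean count per 0.25 m² quadrat over the eligible set
  (12 low-marsh + 6 sill quadrats at LS; 12 low-marsh at NM), scaled to
  m⁻². Periwinkles, burrows and cordgrass use low-marsh quadrats only.
- **Nekton**: biomass (g) summed over gears and both survey years;
  abundances computed per year and averaged; taxonomic distinctness
  averaged over the years in which it is defined (with a warning when a
  year is missing).
- **Taxonomic distinctness**: the abundance-weighted variant
  Δ* = Σ_{i<j} ω_ij x_i x_j / Σ_{i<j} x_i x_j with equal step lengths
  between adjacent taxonomic levels, scaled so species sharing no
  level sit 100 apart. The presence/absence variant Δ⁺ is available via
  `presence_only=True`. Single-species samples are undefined and
  propagate as NaN.
- **Herons**: total deduplicated observation seconds divided by total
  recording seconds (a ratio in [0, 1]).
- **Terrapin**: unique heads within the effective detection radius per
  hour of observation.

## The age model

Net score y_i of pair i is modelled as Normal(β₀ + β₁ ln x_i, σ) with
x_i the shoreline age in years (2–16 on the default grid), priors
β₀ ~ N(0, 1), β₁ ~ N(0.25, 0.75) and σ ~ Gamma(1, 1). The second
argument of the normal priors is a **standard deviation**, and
Gamma(1,1) is shape/rate (an Exponential(1)); both follow the
convention of the mainstream Bayesian regression packages. The
logarithmic mean stands in for a saturating approach to equivalence
with only three parameters — appropriate at n = 13 — and age enters in
years, uncentered, through the natural log.

Sampling uses an adaptive Gaussian random-walk Metropolis kernel,
vectorized across 4 independent chains, default 50,000 iterations per
chain of which 5,000 are warm-up (a config switch controls whether the
total includes warm-up, since that phrasing is ambiguous in common
reporting; the default counts warm-up inside the total). Proposal step
size (targeting ≈0.3 acceptance) and per-parameter proposal scales
(from the rolling warm-up spread) adapt during warm-up only, so the
post-warm-up kernel is fixed and valid. Retained draws are thinned by
5 by default to bound memory in the pointwise log-likelihood matrix.
For this small unimodal posterior the kernel gives split-R̂ < 1.01 and
bulk ESS in the thousands; diagnostics come from arviz and a
convergence failure is reported as a warning with draws still
returned. Runs are bit-reproducible given the seed. Two independent
oracles guard correctness in the tests: a dense-grid quadrature
posterior (means agree within 2% of the posterior SD at n = 13) and
prior recovery with the likelihood switched off.

Model comparison uses PSIS-LOO via arviz (LOOIC = −2·elpd_loo, lower
is better; Pareto k > 0.7 reported as a warning). An exact 13-refit
leave-one-out oracle is cheap at this n and is checked against PSIS in
the tests. Posterior predictive checks simulate replicate datasets
from posterior draws and report the quantile position of the observed
mean and SD.

## Distance sampling

Point-transect geometry: observed radial distances have density
f(r) ∝ r·g(r) on (0, w]. Keys: half-normal
g(r) = exp(−r²/2σ²) and hazard-rate g(r) = 1 − exp(−(r/σ)^−b) with
b > 1 enforced by a log(b−1) parameterization (b near 1 triggers a
boundary warning). Series adjustments (cosine, simple polynomial,
Hermite) multiply the key as 1 + Σ a_j p_j(r/w), rescaled to keep
g(0) = 1, with 0–2 terms per series chosen by AIC and a positivity
penalty on a probe grid; adjustments are skipped when covariates are
on the scale, the usual convention. Covariates enter as
σ = exp(β₀ + βᵀz) with z-standardization for optimizer stability.

The half-normal normalizing integral has the closed form
σ²(1 − exp(−w²/2σ²)); all other cases use 64-node Gauss–Legendre
quadrature (validated against adaptive quadrature to 1e−8 in the
tests). Optimization is Nelder–Mead with up to three jittered starts.

Truncation retains the max(1, floor(0.95·n)) smallest distances (so
178 observations retain 169), with ties at the cutoff broken by
record order. Goodness-of-fit is a χ² test on 6 equal-count distance
bins with df = bins − 1 − k; the bin count is a package decision.
Model selection takes the lowest-AIC candidate among those with GoF
p ≥ 0.05, falling back to the overall lowest AIC with a warning.

The effective detection radius ρ = sqrt(2∫₀ʷ r g(r) dr) — the radius
at which expected missed animals inside equal expected detections
beyond — is evaluated at the reference covariate level (z = 0) and
carries a percentile bootstrap CI (default 999 resamples; refits are
warm-started at the full-data optimum).

## Synthetic-data generator

The generator emulates the *statistical structure* of the 13-pair
design: default ages (7, 4, 2, 7, 10, 9, 12, 7, 3, 16, 9, 6, 16) years,
and per-metric replicate plans (3 soil cores; 18 LS / 12 NM quadrats
for bivalves with sill labels on the last six LS quadrats; 12
quadrats for low-marsh-only taxa; 24 nekton hauls across two years;
4 camera/visual surveys). Site means follow a hierarchical model —
baseline + shared pair effect (among-pair CV 0.30) + independent site
noise (CV 0.15) — and replicates are drawn with within-site CV 0.40
around the site mean. The CVs are package defaults chosen to give
realistic overdispersion and pair-level Z noise of order 1; no
distributional forms are published for any metric, so the noise
families are implementation choices that respect each metric's
support: truncated normal for soil percentages and the 0–100 diversity
index, lognormal for densities/abundances/biomasses/CPUE, gamma for
the heron use ratio. True standardized offsets δ_m shift LS site means
in units of the SD the metric's Z-score divides by; under δ = 0 the
site types are exchangeable, so Z-scores are symmetric about zero by
construction. Each metric draws from its own RNG substream keyed by
registry position, so the replicate plan of one metric never perturbs
another's draws. The low-marsh-only mussel variant is derived from the
same simulated mussel quadrats rather than redrawn.

What the generator does **not** emulate: spatial autocorrelation along
the shoreline, species-level composition (taxonomic distinctness is
simulated as a site-level index, not assembled from catches),
detection error in quadrat counts, inter-annual environmental trends,
and any age dependence unless explicitly requested via `age_slope`.
Passing tests therefore demonstrate the correctness and calibration of
the *scoring machinery* under a plausible data-generating process, not
field validity of any particular dataset.

The terrapin simulator places animals uniformly over the disc of
radius w (radial density ∝ r) and thins them by g(r; σᵢ), with an
optional wind effect on ln σ; with g ≡ 1 the distance CDF is (r/w)²,
which the tests verify.

## Problem sizes and tolerances

The test-suite and acceptance script run at sizes chosen to keep the
whole battery a few minutes on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances: 500 simulated studies for the
null-centering check (grand mean within 3 SE of 0), n = 200 for
age-effect parameter recovery (within 3 posterior SDs), n ≈ 2000–3400
simulated sightings for detection-scale recovery (within 3 SE),
reduced chains (4 × 4,000–30,000) where only convergence plumbing is
under test, and full-length chains where posterior moments are
compared to the grid oracle. Closed-form identities are asserted at
1e−8–1e−12.

## Known limitations

- The Metropolis sampler is tuned for this 3-parameter model; it is
  not a general-purpose MCMC engine and would mix slowly on stiff,
  high-dimensional posteriors.
- Detection-function expansions are limited to two adjustment terms
  and are not combined with covariates.
- The equivalence criterion |Z| < 1 is a fixed convention of the
  method, not an inferential test; no multiplicity adjustment or TOST
  is provided by design.
- Juvenile/forage classification is taken from input labels;
  species-specific length thresholds are out of scope.
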