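# marshequiv

Multi-metric functional-equivalence analysis for constructed **living
shorelines** versus paired **natural fringing marshes**.

Living shorelines — created marshes built from graded bank, clean sand
fill, planted cordgrass (*Spartina alterniflora*) and a stone sill —
are the preferred nature-based alternative to shoreline armoring. The
open question for coastal managers is whether they deliver the same
ecosystem functions as the natural fringing marshes they stand in for.
`marshequiv` implements the full statistical pipeline used to answer
that question for a 13-pair study design spanning 18 ecological
metrics (soil organic matter/C/N/P, bivalve and invertebrate
densities, cordgrass stems, nekton biomass/abundance/taxonomic
distinctness, heron use, and diamondback terrapin counts), and is
aimed at restoration ecologists and biostatisticians who want to score
their own paired monitoring data or study the method's behavior on
simulated designs.

## The method

**Paired Z-scores.** For each metric of each pair, site-level values are
standardized as

    Z = (LS − NM) / σ_pooled

so positive Z favors the living shoreline. Metrics sampled with
identical effort at both sites (soils, invertebrates, plants) use the
*local* pooled SD `σ_L = sqrt((σ²_LS + σ²_NM)/2)` built from within-site
replicate SDs; all others (nekton, herons, terrapin) use the *regional*
pooled SD of the same form built from the among-pair spread of
site-level values. A metric is **functionally equivalent** when
|mean Z| < 1; the mean of a pair's metric scores is its **net
functional-equivalence score** (an auxiliary low-marsh-only mussel
variant is scored but excluded from the net).

**Age model.** Net scores are related to shoreline age by a Bayesian
logarithmic regression

    y_i ~ Normal(β₀ + β₁ ln x_i, σ),
    β₀ ~ N(0,1),  β₁ ~ N(0.25, 0.75),  σ ~ Gamma(1,1)

fitted by MCMC (4 chains × 50,000 iterations, 5,000 warm-up by
default) and compared to the intercept-only null via PSIS-LOO
(LOOIC = −2·elpd_loo), with posterior predictive checks.

**Distance sampling.** Terrapin survey effort is standardized through a
point-transect effective detection radius: after truncating the
farthest 5% of sightings, half-normal and hazard-rate detection
functions (with series expansions and covariates on the scale) are fit
by maximum likelihood, selected by AIC subject to a χ² goodness-of-fit
check, and the selected g(r) yields ρ = sqrt(2 ∫₀ʷ r·g(r) dr) with a
bootstrap CI.

A synthetic-data generator reproduces the study's replication
structure (3 soil cores; 12 low-marsh + 6 sill quadrats; 2 fyke nets +
10 minnow traps over 2 years; 3–6 camera/visual surveys) so every
stage can be exercised and validated end to end without field data.

## Worked example

```sh
python examples/01_simulate_and_score.py
```

simulates a 13-pair study with a −1.5 SD true soils deficit and prints
(abridged):

```
metric-level mean Z (|Z| < 1 means functionally equivalent):
mussels                   -0.13
oysters                   -0.07
organic_matter            -3.65
carbon                    -1.85
nitrogen                  -1.72
phosphorus                -1.77
fish_biomass              -0.15
heron_use                  0.07
terrapin                   0.23
...
grand mean Z = -0.47 +/- 1.61
equivalent metrics: 15/19
```

The four soil metrics are recovered as strongly negative (the injected
construction-legacy deficit of clean sand fill) while every other
metric sits inside the ±1 equivalence band — the qualitative signature
the scoring is designed to expose. `examples/02_age_model.py` fits the
growth and null models and prints β_age with its credible interval and
the LOOIC comparison; `examples/03_distance_sampling.py` walks the
detection-function workflow to an effective radius; and
`examples/04_full_pipeline.py` (or `marshequiv run-all` from a shell)
emits the complete artifact bundle with a reproducibility manifest.

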