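"""Metric registry: definitions of the 18 ecological metrics (plus one
auxiliary variant) and the rules each carries through the analysis.

Each metric knows its SD mode for Z-scoring:

* ``local`` — sampling used identical effort and replication at both
  sites of a pair (soils, invertebrates, plants), so the pooled SD is
  built from the two within-site replicate SDs.
* ``regional`` — effort differed or gears were mixed (nekton, herons,
  terrapin), so the pooled SD is built from the among-pair spread of
  site-level values, one shared value per metric.

The auxiliary low-marsh-only mussel density is scored like any other
metric but excluded from the net functional-equivalence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Noise family used by the synthetic-data generator for each metric class.
# Chosen to respect the metric's support: percentages are (truncated)
# normal, densities/abundances/biomasses are lognormal, the heron use
# ratio is gamma-distributed (small positive ratios), terrapin CPUE is
# lognormal.
_FAMILIES = ("normal", "lognormal", "gamma")


@dataclass(frozen=True)
class MetricDefinition:
    """Everything the pipeline needs to know about one metric."""

    metric_id: str
    label: str
    group: str  # soils | invertebrates | plants | nekton | herons | terrapin
    sd_mode: str  # local | regional
    units: str
    noise_family: str = "lognormal"
    include_in_net: bool = True
    # replicate plan: (n_replicates_LS, n_replicates_NM); years handled
    # by the generator for nekton.
    n_rep_ls: int = 3
    n_rep_nm: int = 3
    # typical site-level value used as the generator's baseline, in
    # metric units (order of magnitude of published raw data).
    baseline: float = 1.0

    def __post_init__(self):
        if self.sd_mode not in ("local", "regional"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.noise_family not in _FAMILIES:
            raise ValueError(f"unknown noise family {self.noise_family!r}")


def _m(*args, **kw) -> MetricDefinition:
    return MetricDefinition(*args, **kw)


#: Registry order is fixed; the generator derives per-metric RNG
#: substreams from each metric's position, so appending a metric never
#: perturbs draws for existing ones.
METRICS: tuple[MetricDefinition, ...] = (
    # Benthic invertebrates & plants: 0.25 m^2 quadrats, 12 low-marsh at
    # both site types plus 6 sill quadrats at LS.  Bivalves use all
    # eligible quadrats; periwinkles/burrows/cordgrass low marsh only.
    _m("mussels", "Ribbed mussel density", "invertebrates", "local",
       "ind m-2", "lognormal", n_rep_ls=18, n_rep_nm=12, baseline=20.0),
    _m("mussels_lm_only", "Ribbed mussel density (low marsh only)",
       "invertebrates", "local", "ind m-2", "lognormal",
       include_in_net=False, n_rep_ls=12, n_rep_nm=12, baseline=20.0),
    _m("oysters", "Oyster density", "invertebrates", "local",
       "ind m-2", "lognormal", n_rep_ls=18, n_rep_nm=12, baseline=2.0),
    _m("periwinkles", "Marsh periwinkle density", "invertebrates", "local",
       "ind m-2", "lognormal", n_rep_ls=12, n_rep_nm=12, baseline=30.0),
    _m("burrows", "Crab burrow density", "invertebrates", "local",
       "burrows m-2", "lognormal", n_rep_ls=12, n_rep_nm=12, baseline=15.0),
    _m("cordgrass", "Cordgrass stem density", "plants", "local",
       "stems m-2", "lognormal", n_rep_ls=12, n_rep_nm=12, baseline=100.0),
    # Soils: three cores per site, each core already reduced to its
    # depth-weighted 0-20 cm mean, reported as weight percent.
    _m("organic_matter", "Soil organic matter", "soils", "local",
       "%", "normal", n_rep_ls=3, n_rep_nm=3, baseline=6.0),
    _m("carbon", "Soil carbon", "soils", "local",
       "%", "normal", n_rep_ls=3, n_rep_nm=3, baseline=2.0),
    _m("nitrogen", "Soil nitrogen", "soils", "local",
       "%", "normal", n_rep_ls=3, n_rep_nm=3, baseline=0.15),
    _m("phosphorus", "Soil phosphorus", "soils", "local",
       "%", "normal", n_rep_ls=3, n_rep_nm=3, baseline=0.05),
    # Nekton: 2 fyke nets + 10 minnow traps per site per year, 2 years.
    # Gear mixing precludes a local SD, so all are regional.
    _m("fish_biomass", "Fish biomass", "nekton", "regional",
       "g", "lognormal", n_rep_ls=24, n_rep_nm=24, baseline=800.0),
    _m("crab_biomass", "Blue crab biomass", "nekton", "regional",
       "g", "lognormal", n_rep_ls=24, n_rep_nm=24, baseline=300.0),
    _m("shrimp_biomass", "Shrimp biomass", "nekton", "regional",
       "g", "lognormal", n_rep_ls=24, n_rep_nm=24, baseline=60.0),
    _m("fish_abundance", "Fish abundance", "nekton", "regional",
       "ind", "lognormal", n_rep_ls=24, n_rep_nm=24, baseline=120.0),
    _m("juvenile_fish_abundance", "Juvenile fish abundance", "nekton",
       "regional", "ind", "lognormal", n_rep_ls=24, n_rep_nm=24,
       baseline=40.0),
    _m("forage_fish_abundance", "Forage fish abundance", "nekton",
       "regional", "ind", "lognormal", n_rep_ls=24, n_rep_nm=24,
       baseline=80.0),
    _m("fish_diversity", "Nekton taxonomic distinctness", "nekton",
       "regional", "0-100", "normal", n_rep_ls=2, n_rep_nm=2,
       baseline=60.0),
    # Herons: 3-6 camera surveys across two seasons; effort-adjusted
    # observation-time ratio per site.
    _m("heron_use", "Heron use (observation/recording time)", "herons",
       "regional", "ratio", "gamma", n_rep_ls=4, n_rep_nm=4,
       baseline=0.02),
    # Terrapin: 3-6 visual surveys; head count per observation hour
    # within the effective radius.
    _m("terrapin", "Terrapin heads per hour", "terrapin", "regional",
       "hr-1", "lognormal", n_rep_ls=4, n_rep_nm=4, baseline=1.0),
)

METRIC_IDS: tuple[str, ...] = tuple(m.metric_id for m in METRICS)
METRICS_BY_ID: dict[str, MetricDefinition] = {m.metric_id: m for m in METRICS}

#: Metrics entering the net functional-equivalence score (18 of 19).
NET_SCORE_METRICS: tuple[str, ...] = tuple(
    m.metric_id for m in METRICS if m.include_in_net
)


def get_metric(metric_id: str) -> MetricDefinition:
    try:
        return METRICS_BY_ID[metric_id]
    except KeyError:
        raise KeyError(
            f"unknown metric {metric_id!r}; known metrics: {', '.join(METRIC_IDS)}"
        ) from None
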