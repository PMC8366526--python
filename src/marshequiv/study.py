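"""Design constants of the 13-pair Chesapeake Bay living-shoreline survey.

The study compared thirteen constructed living shorelines (LS) — graded
bank, sand fill, planted cordgrass, stone sill — to paired natural
fringing marshes (NM) across coastal Virginia on 18 ecological metrics
spanning soils, benthic invertebrates, plants, nekton, herons and
diamondback terrapin.  The constants below are the published design
facts the rest of the package builds on: the ages of the living
shorelines (years since construction at the time of the survey) and the
published metric-level mean Z-scores, used as reference inputs where a
computation starts from the printed summary rather than raw data.
"""

from __future__ import annotations

# Years since construction for pairs 1..13.
SITE_AGES_YEARS: tuple[int, ...] = (7, 4, 2, 7, 10, 9, 12, 7, 3, 16, 9, 6, 16)

N_PAIRS = 13

# Published metric-level mean Z-scores (mean over the 13 pairs).  The
# low-marsh-only mussel variant is an auxiliary column excluded from the
# net functional-equivalence score.
PUBLISHED_METRIC_SCORES: dict[str, float] = {
    "mussels": -0.20,
    "mussels_lm_only": -0.80,
    "oysters": 0.28,
    "periwinkles": -0.12,
    "burrows": 0.02,
    "cordgrass": -0.14,
    "organic_matter": -1.86,
    "carbon": -2.61,
    "nitrogen": -2.60,
    "phosphorus": -1.76,
    "fish_biomass": 0.85,
    "crab_biomass": 0.46,
    "shrimp_biomass": 0.28,
    "fish_abundance": 0.48,
    "juvenile_fish_abundance": 0.06,
    "forage_fish_abundance": 0.09,
    "fish_diversity": -0.12,
    "heron_use": 0.49,
    "terrapin": 0.27,
}


def published_grand_mean() -> float:
    """Unweighted mean of the 18 published metric scores.

    The auxiliary low-marsh-only mussel variant is excluded, matching
    how the net functional-equivalence score is defined.
    """
    scores = [v for k, v in PUBLISHED_METRIC_SCORES.items() if k != "mussels_lm_only"]
    return sum(scores) / len(scores)
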