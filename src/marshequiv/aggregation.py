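"""Replicate-level observations -> site-level metric summaries.

Each ecological metric has a stated aggregation rule taking the raw
field replicates (soil cores, quadrats, net hauls, camera segments,
visual surveys) to one site-level value, plus — for metrics sampled with
identical effort at both members of a pair — a within-site SD:

* soils: thickness-weighted 0-20 cm mean per core, then mean/SD over the
  three cores;
* bivalves: mean count per 0.25 m^2 quadrat over the eligible quadrat
  set (low marsh + sill at living shorelines, low marsh at natural
  marshes), converted to individuals per m^2;
* nekton: biomass summed over gears and the two survey years; abundance
  and taxonomic distinctness computed per year then averaged;
* herons: total observation time divided by total recording time;
* terrapin: unique head count within the effective radius per hour of
  observation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteProfileError, MarshEquivError, ValidationError

#: Quadrat area used for all invertebrate/plant counts.
QUADRAT_AREA_M2 = 0.25

#: The three soil core sections, cm below the marsh surface.
SOIL_SECTIONS = ((0.0, 5.0), (5.0, 10.0), (10.0, 20.0))


@dataclass(frozen=True)
class SiteMetricSummary:
    """Site-level value of one metric at one member of one pair.

    ``sd`` is None for metrics whose pooled SD is regional (among-pair):
    a within-site SD either cannot be computed consistently or is not
    used.
    """

    pair: int
    site_type: str  # "LS" | "NM"
    metric: str
    mean: float
    sd: float | None
    n: int


# ---------------------------------------------------------------------------
# soils


def soil_profile_mean(sections: Sequence[tuple[tuple[float, float], float]]) -> float:
    """Thickness-weighted mean of a 0-20 cm soil core.

    ``sections`` maps depth intervals (cm) to measured weight percent;
    the full profile 0-5, 5-10, 10-20 cm must be present.  The weighted
    mean is (5*v1 + 5*v2 + 10*v3) / 20.
    """
    by_interval = {tuple(iv): float(v) for iv, v in sections}
    missing = [iv for iv in SOIL_SECTIONS if iv not in by_interval]
    if missing:
        gaps = ", ".join(f"{a:g}-{b:g} cm" for a, b in missing)
        raise IncompleteProfileError(f"soil core is missing section(s): {gaps}")
    num = sum((b - a) * by_interval[(a, b)] for a, b in SOIL_SECTIONS)
    return num / 20.0


# ---------------------------------------------------------------------------
# generic replicate summary


def site_summary(values: Iterable[float]) -> tuple[float, float | None, int]:
    """Arithmetic mean, sample SD (n-1), and n of replicate values.

    SD is None when only one replicate is available.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise MarshEquivError("site_summary requires at least one replicate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd, int(arr.size)


# ---------------------------------------------------------------------------
# benthic invertebrates


def bivalve_density(
    quadrat_counts: Sequence[float],
    zones: Sequence[str],
    site_type: str,
    lm_only: bool = False,
    quadrat_area_m2: float = QUADRAT_AREA_M2,
) -> tuple[float, float | None, int]:
    """Bivalve density (individuals per m^2) from quadrat counts.

    At living shorelines the main metric pools low-marsh and sill
    quadrats; the auxiliary low-marsh-only variant (``lm_only``) and all
    natural-marsh densities use low-marsh quadrats alone.  Natural
    marshes have no sill, so sill-labelled quadrats there are an error.
    """
    counts = np.asarray(quadrat_counts, dtype=float)
    zones = list(zones)
    if counts.size != len(zones):
        raise ValidationError(["quadrat_counts and zones differ in length"])
    bad = sorted(set(zones) - {"low_marsh", "sill"})
    if bad:
        raise ValidationError([f"unknown zone label(s): {bad}"])
    if site_type == "NM" and "sill" in zones:
        raise ValidationError(["natural marsh sites have no sill zone"])
    if site_type == "NM" or lm_only:
        keep = [z == "low_marsh" for z in zones]
    else:
        keep = [True] * len(zones)
    dens = counts[np.asarray(keep)] / quadrat_area_m2
    if dens.size == 0:
        raise MarshEquivError("no eligible quadrats for this metric")
    sd = float(dens.std(ddof=1)) if dens.size > 1 else None
    return float(dens.mean()), sd, int(dens.size)


# ---------------------------------------------------------------------------
# taxonomic distinctness


def taxonomic_distinctness(
    abundances: Mapping[str, float],
    taxonomy: Mapping[str, Sequence[str]],
    presence_only: bool = False,
) -> float:
    """Abundance-weighted taxonomic distinctness Delta* on a 0-100 scale.

    ``taxonomy`` maps each species to its classification path ordered
    coarse -> fine (e.g. ``("Actinopterygii", "Fundulidae", "Fundulus")``),
    excluding the species name itself.  Path weights use equal step
    lengths between adjacent taxonomic levels, scaled so that two
    species sharing no level are 100 apart; two congeners sit one step
    apart (the minimum nonzero weight).

    Delta* = sum_{i<j} w_ij x_i x_j / sum_{i<j} x_i x_j.  With
    ``presence_only`` all abundances are replaced by 1 (the
    presence/absence variant Delta+).

    A single-species sample has no between-species pairs: the index is
    undefined and NaN is returned (callers propagate it as missing).
    """
    species = [s for s, x in abundances.items() if x > 0]
    if len(species) < 2:
        warnings.warn("taxonomic distinctness undefined for <2 species; returning NaN")
        return math.nan
    paths = {}
    depth = None
    for s in species:
        if s not in taxonomy:
            raise ValidationError([f"species {s!r} missing from taxonomy"])
        p = tuple(taxonomy[s])
        if depth is None:
            depth = len(p)
        elif len(p) != depth:
            raise ValidationError(
                [f"taxonomy depth mismatch for {s!r}: {len(p)} vs {depth}"]
            )
        paths[s] = p
    # tree height includes the species level itself
    height = depth + 1
    num = 0.0
    den = 0.0
    for i, si in enumerate(species):
        for sj in species[i + 1:]:
            shared = 0
            for a, b in zip(paths[si], paths[sj]):
                if a != b:
                    break
                shared += 1
            w = 100.0 * (height - shared) / height
            xi = 1.0 if presence_only else float(abundances[si])
            xj = 1.0 if presence_only else float(abundances[sj])
            num += w * xi * xj
            den += xi * xj
    return num / den


# ---------------------------------------------------------------------------
# nekton


def nekton_aggregates(catch: pd.DataFrame) -> dict[str, float]:
    """Site-level nekton metrics from tagged catch records.

    ``catch`` columns: ``year``, ``gear``, ``group`` (fish | crab |
    shrimp), ``count``, ``biomass_g`` and optional boolean ``juvenile``
    / ``forage`` flags, plus optional per-year ``diversity`` values.

    Biomass is summed over both gears and both years; abundances are
    computed per year then averaged across years; diversity (already a
    per-year site value) is averaged across the years in which it is
    defined, with a warning if a year is missing.
    """
    required = {"year", "gear", "group", "count", "biomass_g"}
    missing = required - set(catch.columns)
    if missing:
        raise ValidationError([f"catch records missing column(s): {sorted(missing)}"])
    if catch["year"].isna().any():
        raise ValidationError(["catch records contain rows with no year tag"])
    out: dict[str, float] = {}
    for group, key in (("fish", "fish_biomass"), ("crab", "crab_biomass"),
                       ("shrimp", "shrimp_biomass")):
        out[key] = float(catch.loc[catch["group"] == group, "biomass_g"].sum())

    fish = catch[catch["group"] == "fish"]
    years = sorted(catch["year"].unique())

    def _per_year_mean(frame: pd.DataFrame) -> float:
        per_year = [float(frame.loc[frame["year"] == y, "count"].sum()) for y in years]
        return float(np.mean(per_year)) if per_year else 0.0

    out["fish_abundance"] = _per_year_mean(fish)
    for flag, key in (("juvenile", "juvenile_fish_abundance"),
                      ("forage", "forage_fish_abundance")):
        sub = fish[fish[flag]] if flag in fish.columns else fish.iloc[0:0]
        out[key] = _per_year_mean(sub)

    if "diversity" in catch.columns:
        div = catch.dropna(subset=["diversity"]).groupby("year")["diversity"].first()
        if len(div) and len(div) < len(years):
            warnings.warn(
                "diversity available for only "
                f"{len(div)}/{len(years)} years; averaging available years"
            )
        out["fish_diversity"] = float(div.mean()) if len(div) else math.nan
    return out


# ---------------------------------------------------------------------------
# herons & terrapin


def heron_adjusted_time(observed_seconds: float, recorded_seconds: float) -> float:
    """Effort-adjusted heron use: observation time / recording time.

    Detections simultaneous on multiple cameras are assumed already
    deduplicated, so the ratio must lie in [0, 1].
    """
    if recorded_seconds <= 0:
        raise MarshEquivError("total recording time must be positive")
    if observed_seconds < 0:
        raise MarshEquivError("observed time cannot be negative")
    if observed_seconds > recorded_seconds:
        raise MarshEquivError(
            "observed time exceeds recording time; simultaneous detections "
            "must be deduplicated before aggregation"
        )
    return observed_seconds / recorded_seconds


def terrapin_cpue(heads_within_ers: float, observation_hours: float) -> float:
    """Terrapin head count per hour of observation.

    ``heads_within_ers`` counts unique individuals detected within the
    effective radius surveyed.
    """
    if observation_hours <= 0:
        raise MarshEquivError("observation effort must be positive hours")
    if heads_within_ers < 0:
        raise MarshEquivError("head count cannot be negative")
    return heads_within_ers / observation_hours


# ---------------------------------------------------------------------------
# tidy-table driver


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a tidy replicate table to site-level metric summaries.

    ``table`` columns: pair, site_type, metric, replicate, value (as
    produced by :func:`marshequiv.synthetic.simulate_study` or a real
    replicate export matching that schema).  Returns one row per
    (pair, site_type, metric) with mean, sd, n.  Within-site SDs are
    reported for every metric here; the equivalence stage decides (per
    metric definition) whether the local SD may actually be used.
    """
    required = {"pair", "site_type", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError([f"replicate table missing column(s): {sorted(missing)}"])
    grp = table.groupby(["pair", "site_type", "metric"], sort=True)["value"]
    out = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out
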