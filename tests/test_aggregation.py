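"""Unit tests for the per-metric aggregation rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshequiv import (
    IncompleteProfileError,
    MarshEquivError,
    ValidationError,
    bivalve_density,
    heron_adjusted_time,
    nekton_aggregates,
    site_summary,
    soil_profile_mean,
    taxonomic_distinctness,
    terrapin_cpue,
)
from marshequiv.aggregation import SOIL_SECTIONS


class TestSoilProfile:
    @pytest.mark.parametrize("values, expected", [
        ((3.0, 3.0, 3.0), 3.0),            # constant profile
        ((4.0, 2.0, 1.0), 2.0),            # (20 + 10 + 10) / 20
        ((1.0, 0.0, 0.0), 0.25),
    ])
    def test_thickness_weighted_mean(self, values, expected):
        core = list(zip(SOIL_SECTIONS, values))
        assert soil_profile_mean(core) == pytest.approx(expected)

    def test_incomplete_profile_names_gap(self):
        core = [((0.0, 5.0), 2.0), ((5.0, 10.0), 2.0)]
        with pytest.raises(IncompleteProfileError, match="10-20 cm"):
            soil_profile_mean(core)

    @given(st.lists(st.floats(0, 50), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_mean_bounded_by_sections(self, values):
        core = list(zip(SOIL_SECTIONS, values))
        m = soil_profile_mean(core)
        assert min(values) - 1e-12 <= m <= max(values) + 1e-12


class TestSiteSummary:
    @pytest.mark.parametrize("values, expected", [
        ([2, 2, 2], (2.0, 0.0, 3)),
        ([1, 2, 3], (2.0, 1.0, 3)),
    ])
    def test_mean_sample_sd(self, values, expected):
        assert site_summary(values) == pytest.approx(expected)

    def test_single_replicate_has_no_sd(self):
        mean, sd, n = site_summary([5.0])
        assert (mean, n) == (5.0, 1) and sd is None

    def test_empty_rejected(self):
        with pytest.raises(MarshEquivError):
            site_summary([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_two_pass_oracle(self, values):
        """Streaming mean/SD agree with an explicit two-pass computation."""
        mean, sd, n = site_summary(values)
        m = sum(values) / len(values)
        s = math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))
        assert mean == pytest.approx(m, rel=1e-12, abs=1e-9)
        assert sd == pytest.approx(s, rel=1e-12, abs=1e-9)


class TestBivalveDensity:
    def test_unit_conversion(self):
        # 12 quadrats of 0.25 m^2, one mussel each -> 4 per m^2
        mean, _, n = bivalve_density([1] * 12, ["low_marsh"] * 12, "NM")
        assert mean == pytest.approx(4.0) and n == 12

    def test_zone_eligibility_at_living_shorelines(self):
        counts = [0] * 12 + [5] * 6
        zones = ["low_marsh"] * 12 + ["sill"] * 6
        main, _, n_main = bivalve_density(counts, zones, "LS")
        lm, _, n_lm = bivalve_density(counts, zones, "LS", lm_only=True)
        assert n_main == 18 and n_lm == 12
        assert main == pytest.approx((30 / 18) / 0.25)
        assert lm == 0.0

    def test_oysters_only_on_sill_gives_zero_lm_density(self):
        counts = [0] * 12 + [2, 1, 3, 0, 1, 2]
        zones = ["low_marsh"] * 12 + ["sill"] * 6
        lm, _, _ = bivalve_density(counts, zones, "LS", lm_only=True)
        main, _, _ = bivalve_density(counts, zones, "LS")
        assert lm == 0.0 and main > 0.0

    def test_nm_with_sill_rejected(self):
        with pytest.raises(ValidationError, match="sill"):
            bivalve_density([1, 2], ["low_marsh", "sill"], "NM")

    def test_pooled_at_least_lm_when_sill_richer(self):
        counts = [1] * 12 + [4] * 6
        zones = ["low_marsh"] * 12 + ["sill"] * 6
        main, _, _ = bivalve_density(counts, zones, "LS")
        lm, _, _ = bivalve_density(counts, zones, "LS", lm_only=True)
        assert main >= lm


TAXONOMY = {
    # path coarse -> fine: (class, family, genus)
    "Fundulus heteroclitus": ("Actinopterygii", "Fundulidae", "Fundulus"),
    "Fundulus majalis": ("Actinopterygii", "Fundulidae", "Fundulus"),
    "Menidia menidia": ("Actinopterygii", "Atherinopsidae", "Menidia"),
    "Callinectes sapidus": ("Malacostraca", "Portunidae", "Callinectes"),
}


class TestTaxonomicDistinctness:
    def test_maximal_separation_scales_to_100(self):
        ab = {"Fundulus heteroclitus": 5, "Callinectes sapidus": 5}
        assert taxonomic_distinctness(ab, TAXONOMY) == pytest.approx(100.0)

    def test_congeners_sit_one_step_apart(self):
        ab = {"Fundulus heteroclitus": 3, "Fundulus majalis": 9}
        # one step of a four-level tree (3 ranks + species level)
        assert taxonomic_distinctness(ab, TAXONOMY) == pytest.approx(25.0)

    def test_three_species_matches_brute_force(self):
        ab = {"Fundulus heteroclitus": 4.0, "Menidia menidia": 2.0,
              "Callinectes sapidus": 1.0}
        # enumerate all pairs directly
        w = {("Fundulus heteroclitus", "Menidia menidia"): 75.0,
             ("Fundulus heteroclitus", "Callinectes sapidus"): 100.0,
             ("Menidia menidia", "Callinectes sapidus"): 100.0}
        num = sum(wij * ab[i] * ab[j] for (i, j), wij in w.items())
        den = sum(ab[i] * ab[j] for (i, j) in w)
        assert taxonomic_distinctness(ab, TAXONOMY) == pytest.approx(num / den)

    def test_single_species_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(
                taxonomic_distinctness({"Menidia menidia": 3}, TAXONOMY))

    def test_mismatched_depth_rejected(self):
        bad = dict(TAXONOMY)
        bad["Menidia menidia"] = ("Actinopterygii", "Atherinopsidae")
        ab = {"Fundulus heteroclitus": 1, "Menidia menidia": 1}
        with pytest.raises(ValidationError, match="depth"):
            taxonomic_distinctness(ab, bad)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_abundance_rescaling(self, c):
        ab = {"Fundulus heteroclitus": 4.0, "Menidia menidia": 2.0,
              "Callinectes sapidus": 1.0}
        base = taxonomic_distinctness(ab, TAXONOMY)
        scaled = taxonomic_distinctness({k: v * c for k, v in ab.items()},
                                        TAXONOMY)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 100.0


def _catch(year, group, count, biomass, **kw):
    return {"year": year, "gear": "fyke", "group": group, "count": count,
            "biomass_g": biomass, **kw}


class TestNektonAggregates:
    def test_biomass_summed_abundance_averaged(self):
        rows = [_catch(2018, "fish", 10, 100.0, juvenile=True, forage=False),
                _catch(2019, "fish", 20, 100.0, juvenile=False, forage=True)]
        out = nekton_aggregates(pd.DataFrame(rows))
        assert out["fish_biomass"] == pytest.approx(200.0)
        assert out["fish_abundance"] == pytest.approx(15.0)
        assert out["juvenile_fish_abundance"] == pytest.approx(5.0)
        assert out["forage_fish_abundance"] == pytest.approx(10.0)

    def test_identical_years_double_biomass_same_abundance(self):
        rows = [_catch(y, g, c, b) for y in (2018, 2019)
                for g, c, b in (("fish", 10, 50.0), ("crab", 2, 30.0),
                                ("shrimp", 5, 8.0))]
        out = nekton_aggregates(pd.DataFrame(rows))
        assert out["crab_biomass"] == pytest.approx(60.0)
        assert out["shrimp_biomass"] == pytest.approx(16.0)
        assert out["fish_abundance"] == pytest.approx(10.0)

    def test_diversity_single_year_averaged_with_warning(self):
        rows = [_catch(2018, "fish", 10, 50.0, diversity=62.0),
                _catch(2019, "fish", 10, 50.0, diversity=np.nan)]
        with pytest.warns(UserWarning, match="diversity"):
            out = nekton_aggregates(pd.DataFrame(rows))
        assert out["fish_diversity"] == pytest.approx(62.0)

    def test_missing_year_rejected(self):
        rows = [_catch(None, "fish", 1, 1.0)]
        with pytest.raises(ValidationError, match="year"):
            nekton_aggregates(pd.DataFrame(rows))


class TestEffortRatios:
    @pytest.mark.parametrize("obs, rec, expected", [
        (0.0, 1000.0, 0.0),
        (1800.0, 36000.0, 0.05),
    ])
    def test_heron_ratio(self, obs, rec, expected):
        assert heron_adjusted_time(obs, rec) == pytest.approx(expected)

    def test_heron_rejects_zero_recording_and_excess_observation(self):
        with pytest.raises(MarshEquivError):
            heron_adjusted_time(10.0, 0.0)
        with pytest.raises(MarshEquivError, match="dedup"):
            heron_adjusted_time(200.0, 100.0)

    @pytest.mark.parametrize("heads, hours, expected", [
        (0, 5.0, 0.0),
        (6, 3.0, 2.0),
    ])
    def test_terrapin_cpue(self, heads, hours, expected):
        assert terrapin_cpue(heads, hours) == pytest.approx(expected)

    def test_terrapin_cpue_requires_positive_effort(self):
        with pytest.raises(MarshEquivError):
            terrapin_cpue(3, 0.0)
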