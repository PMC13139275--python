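import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrisk.data_model import ConfigurationError, DomainError, summarize
from sedrisk.indices import (
    DEFAULT_SCHEMES,
    ClassificationScheme,
    assess_survey,
    cd_scheme,
    classify,
    contamination_degree,
    contamination_factor,
    ecological_risk_factor,
    enrichment_factor,
    geoaccumulation_index,
    pollution_load_index,
    risk_index,
)
from sedrisk.references import BackgroundSet, DEFAULT_TOXICITY

from conftest import make_survey

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)

# contamination factors printed for the most impacted wet-season site-season
# downstream of the first wastewater discharge (metals As, Cr, Cu, Fe, Zn)
SITE_D_WET_CFS = (0.25, 4.03, 1.22, 0.43, 1.18)


class TestElementaryIndices:
    def test_contamination_factor_is_the_background_ratio(self):
        assert contamination_factor(10, 5) == 2.0
        assert contamination_factor(7.3, 7.3) == 1.0
        with pytest.raises(DomainError):
            contamination_factor(1.0, 0.0)

    def test_enrichment_factor_definition(self):
        # metal at exactly background ratios
        assert enrichment_factor(13, 47200, 13, 47200) == 1.0
        # the reference metal against itself
        assert enrichment_factor(5.0, 5.0, 47200, 47200) == 1.0
        # doubling the numerator only
        assert enrichment_factor(2 * 13, 47200, 13, 47200) == 2.0
        with pytest.raises(DomainError):
            enrichment_factor(1.0, 0.0, 1.0, 1.0)

    def test_geoaccumulation_zero_at_one_and_a_half_background(self):
        assert geoaccumulation_index(1.5 * 21.6, 21.6) == pytest.approx(0.0)

    @pytest.mark.parametrize("cf,expected", [(2.44, 0.70), (0.97, -0.63), (2.71, 0.85)])
    def test_geoaccumulation_matches_published_anchor_cells(self, cf, expected):
        # published Igeo cells are log2(CF/1.5) printed at 2 decimals
        assert round(geoaccumulation_index(cf, 1.0), 2) == expected

    def test_pollution_load_index_is_the_geometric_mean(self):
        assert pollution_load_index([3.0, 3.0, 3.0]) == pytest.approx(3.0)
        assert pollution_load_index([1.0, 4.0]) == pytest.approx(2.0)
        assert pollution_load_index(SITE_D_WET_CFS) == pytest.approx(0.91, abs=0.005)
        with pytest.raises(DomainError):
            pollution_load_index([])
        with pytest.raises(DomainError):
            pollution_load_index([1.0, 0.0])

    def test_contamination_degree_is_the_sum(self):
        assert contamination_degree([1, 1, 1]) == 3.0
        assert contamination_degree([2.5]) == 2.5
        assert contamination_degree(SITE_D_WET_CFS) == pytest.approx(7.11)

    def test_ecological_risk_factor_and_risk_index(self):
        assert ecological_risk_factor(10, 0) == 0.0
        assert ecological_risk_factor(1, 3.3) == 3.3
        assert ecological_risk_factor(2, 4.03) == pytest.approx(8.06)
        trs = (10, 2, 5, 1, 1)
        ers = [ecological_risk_factor(t, cf) for t, cf in zip(trs, SITE_D_WET_CFS)]
        assert risk_index(ers) == pytest.approx(18.27)
        assert risk_index([0, 0]) == 0.0
        assert risk_index([5.0]) == 5.0


class TestAlgebraicProperties:
    @given(positive, positive)
    @settings(max_examples=300, deadline=None)
    def test_igeo_equals_log2_cf_minus_log2_1p5(self, c, b):
        lhs = geoaccumulation_index(c, b)
        rhs = math.log2(contamination_factor(c, b)) - math.log2(1.5)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @given(st.lists(positive, min_size=1, max_size=8))
    @settings(max_examples=300, deadline=None)
    def test_pli_log_space_matches_direct_product(self, cfs):
        direct = float(np.prod(cfs)) ** (1.0 / len(cfs))
        assert pollution_load_index(cfs) == pytest.approx(direct, rel=1e-12)

    @given(st.lists(positive, min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_composites_bracket_the_contamination_factors(self, cfs):
        assert contamination_degree(cfs) >= max(cfs) - 1e-12
        pli = pollution_load_index(cfs)
        assert min(cfs) - 1e-9 <= pli <= max(cfs) + 1e-9

    @given(st.lists(positive, min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_risk_index_reduces_to_cd_at_unit_toxicity(self, cfs):
        ers = [ecological_risk_factor(1.0, cf) for cf in cfs]
        assert risk_index(ers) == pytest.approx(contamination_degree(cfs), rel=1e-12)

    def test_doubling_concentrations(self, rng):
        c = rng.lognormal(2, 1, 100)
        b = rng.lognormal(2, 1, 100)
        ref_c, ref_b = 3.7, 5.1
        np.testing.assert_allclose(contamination_factor(2 * c, b),
                                   2 * contamination_factor(c, b))
        np.testing.assert_allclose(
            geoaccumulation_index(2 * c, b), geoaccumulation_index(c, b) + 1.0,
            rtol=0, atol=1e-12,
        )
        # doubling every concentration (metal and reference) leaves EF fixed
        np.testing.assert_array_equal(
            enrichment_factor(2 * c, 2 * ref_c, b, ref_b),
            enrichment_factor(c, ref_c, b, ref_b),
        )
        cfs = contamination_factor(c, b)
        assert pollution_load_index(2 * cfs) == pytest.approx(
            2 * pollution_load_index(cfs), rel=1e-12
        )
        assert contamination_degree(2 * cfs) == pytest.approx(
            2 * contamination_degree(cfs), rel=1e-12
        )


class TestClassification:
    def test_published_category_examples(self):
        assert classify(4.69, DEFAULT_SCHEMES["CF"]) == "considerable contamination"
        assert classify(0.5, DEFAULT_SCHEMES["PLI"]) == "unpolluted"
        assert classify(-2.0, DEFAULT_SCHEMES["Igeo"]) == "unpolluted"
        assert classify(39.9, DEFAULT_SCHEMES["Er"]) == "low risk"
        assert classify(40.0, DEFAULT_SCHEMES["Er"]) == "moderate risk"

    def test_cd_scheme_scales_with_metal_count(self):
        sch = cd_scheme(5)
        assert sch.classify(4.9) == "low degree of contamination"
        assert sch.classify(5.0) == "moderate degree of contamination"
        assert sch.classify(20.0) == "very high degree of contamination"

    def test_monotone_over_sorted_random_values(self, rng):
        for scheme in DEFAULT_SCHEMES.values():
            values = np.sort(rng.uniform(-10, 700, 500))
            ranks = [scheme.rank(scheme.classify(v)) for v in values]
            assert all(r2 >= r1 for r1, r2 in zip(ranks, ranks[1:]))

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassificationScheme("bad", (1.0, 1.0), ("a", "b", "c"))
        with pytest.raises(ConfigurationError):
            ClassificationScheme("bad", (1.0,), ("a", "a"))
        with pytest.raises(DomainError):
            DEFAULT_SCHEMES["CF"].classify(float("nan"))


class TestAssessSurvey:
    def _background(self):
        return BackgroundSet(
            {"As": 9.3, "Cr": 21.6, "Cu": 40.0, "Fe": 47200.0, "Zn": 56.0}, "Fe"
        )

    def test_everything_at_background(self):
        bg = self._background()
        rows = [
            ("A", "wet", metal, 1, value)
            for metal, value in bg.values.items()
        ]
        res = assess_survey(summarize(make_survey(rows)), bg, DEFAULT_TOXICITY)
        per_metal = res[res["metal"].notna()]
        assert np.allclose(per_metal[per_metal["index"] == "CF"]["value"], 1.0)
        assert np.allclose(per_metal[per_metal["index"] == "EF"]["value"], 1.0)
        assert np.allclose(
            per_metal[per_metal["index"] == "Igeo"]["value"], -math.log2(1.5)
        )
        comp = res[res["metal"].isna()].set_index("index")
        assert comp.loc["PLI", "value"] == pytest.approx(1.0)
        assert comp.loc["CD", "value"] == pytest.approx(5.0)
        assert comp.loc["CD", "n_metals_used"] == 5

    def test_below_lod_metals_leave_blanks_and_shrink_composites(self):
        bg = self._background()
        rows = [
            ("A", "wet", "As", 1, 0.0, True, 0.001),
            ("A", "wet", "Cr", 1, 0.0, True, 0.001),
            ("A", "wet", "Cu", 1, 12.74),
            ("A", "wet", "Fe", 1, 1148.75),
            ("A", "wet", "Zn", 1, 13.05),
        ]
        res = assess_survey(summarize(make_survey(rows)), bg, DEFAULT_TOXICITY)
        cf = res[res["index"] == "CF"]
        assert cf["value"].notna().sum() == 3  # Cu, Fe, Zn only
        assert set(cf[cf["value"].isna()]["metal"]) == {"As", "Cr"}
        comp = res[res["metal"].isna()].set_index("index")
        assert comp.loc["PLI", "n_metals_used"] == 3

    def test_missing_reference_data_names_the_metal(self):
        rows = [("A", "wet", "Cu", 1, 10.0), ("A", "wet", "Fe", 1, 1000.0)]
        summaries = summarize(make_survey(rows))
        with pytest.raises(ConfigurationError, match="Cu"):
            assess_survey(
                summaries, BackgroundSet({"Fe": 47200.0}, "Fe"), DEFAULT_TOXICITY
            )

    def test_synthetic_survey_yields_one_composite_per_site_season(self, default_survey):
        bg = self._background()
        res = assess_survey(summarize(default_survey), bg, DEFAULT_TOXICITY)
        comp = res[res["metal"].isna()]
        counts = comp.groupby("index").size()
        assert counts["PLI"] == counts["CD"] == counts["RI"] == 20
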