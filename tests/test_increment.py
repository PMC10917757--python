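"""Increment temporal adjustment and forest/FAWS gap-filling."""

import numpy as np
import pytest

from forestharm.core import IncrementStats, SoefSeries
from forestharm.increment import (
    fill_components_from_ratio,
    gapfill_increment,
    temporal_adjust_increment,
    totals_from_perha,
)


def soef_with_gai(values, years=(2000, 2005, 2010, 2015, 2020), **extra):
    return SoefSeries(
        country="AA", years=list(years), gai_faws_ha=list(values), **extra
    )


class TestTemporalAdjust:
    def test_two_percent_decline_scales_by_098(self):
        """A -2% change of the reporting-series GAI between the inventory
        period and 2015 reduces the harmonised GAI by the same 2%."""
        # series whose mean over 2000-2009 is 5.0 and 2015 value is 4.9
        s = soef_with_gai([5.0, 5.0, 5.0, 4.9, 4.9])
        gai_mean = s.mean_over("gai_faws_ha", 2000, 2009)
        assert gai_mean == pytest.approx(5.0, abs=0.02)
        gai2, anl2, nai2, adj = temporal_adjust_increment(
            6.0, 0.6, (2000, 2009), s
        )
        assert adj.applied
        assert adj.correction_factor == pytest.approx(4.9 / gai_mean, rel=1e-9)
        assert gai2 == pytest.approx(6.0 * 4.9 / gai_mean, rel=1e-9)

    def test_covered_period_needs_no_adjustment(self):
        s = soef_with_gai([5.0, 5.2, 5.4, 5.6, 5.8])
        gai2, anl2, nai2, adj = temporal_adjust_increment(
            6.0, 0.6, (2010, 2020), s
        )
        assert not adj.applied
        assert (gai2, anl2, nai2) == (6.0, 0.6, 5.4)

    def test_arithmetic_oracle_with_known_factor(self):
        # constant series 5.0 except 5.25 at 2015 -> factor 1.05 exactly
        s = soef_with_gai([5.0, 5.0, 5.0, 5.25, 5.0])
        gai2, anl2, nai2, adj = temporal_adjust_increment(
            6.0, 0.6, (2000, 2005), s
        )
        assert adj.correction_factor == pytest.approx(1.05, rel=1e-12)
        assert gai2 == pytest.approx(6.3)
        assert anl2 == pytest.approx(0.63)
        assert nai2 == pytest.approx(5.67)
        assert gai2 == pytest.approx(nai2 + anl2, abs=1e-9)

    def test_anl_share_is_preserved(self):
        s = soef_with_gai([4.0, 4.4, 4.8, 5.2, 5.6])
        gai2, anl2, _, adj = temporal_adjust_increment(5.0, 0.75, (2000, 2008), s)
        assert anl2 / gai2 == pytest.approx(0.15, rel=1e-12)
        assert adj.anl_gai_ratio == pytest.approx(0.15)

    def test_missing_series_rejected(self):
        s = SoefSeries(country="AA", years=[2000, 2020], forest_area=[1.0, 1.0])
        with pytest.raises(ValueError):
            temporal_adjust_increment(5.0, 0.5, (2000, 2005), s)


class TestTotals:
    @pytest.mark.parametrize("per_ha,area,expected", [(5.0, 1e6, 5e6), (0.0, 1e5, 0.0)])
    def test_total_is_product(self, per_ha, area, expected):
        assert totals_from_perha(per_ha, area) == expected

    def test_vector_against_loop(self, rng):
        per_ha = rng.uniform(1, 10, 20)
        areas = rng.uniform(1e4, 1e6, 20)
        got = [totals_from_perha(p, a) for p, a in zip(per_ha, areas)]
        want = []
        for i in range(20):
            want.append(per_ha[i] * areas[i])
        assert got == pytest.approx(want)


def record_forest_only(gai=5.0, anl=0.5):
    return IncrementStats(
        unit="AA1", ref_year=2015, gai_forest_ha=gai, anl_forest_ha=anl,
        source="NFI",
    )


class TestGapfill:
    def test_similar_areas_copies_per_ha_values(self):
        out = gapfill_increment(record_forest_only(), 1.00e6, 0.95e6)
        assert out.gai_faws_ha == 5.0
        assert out.anl_faws_ha == 0.5
        assert out.uncertainty == 2
        assert out.total("gai", "faws") == pytest.approx(5.0 * 0.95e6)

    def test_soef_cross_category_ratio_branch(self):
        """Areas 30% apart: the SoEF FAWS/forest per-ha NAI ratio (1.11)
        scales the reported value."""
        s = SoefSeries(
            country="AA", years=[2015],
            gai_forest_ha=[5.0], gai_faws_ha=[5.55],
            nai_forest_ha=[4.0], nai_faws_ha=[4.44],
        )
        rec = IncrementStats(
            unit="AA1", ref_year=2015, gai_forest_ha=5.0, anl_forest_ha=1.0,
        )
        out = gapfill_increment(rec, 1.3e6, 1.0e6, soef=s)
        assert out.nai_faws_ha == pytest.approx(4.0 * 1.11, rel=1e-9)
        assert out.gai_faws_ha == pytest.approx(5.0 * 1.11, rel=1e-9)
        assert out.uncertainty == 2
        assert out.gai_faws_ha == pytest.approx(
            out.nai_faws_ha + out.anl_faws_ha, abs=1e-9
        )

    def test_neighbour_ratio_branch_gets_label_3(self):
        out = gapfill_increment(
            record_forest_only(), 1.4e6, 1.0e6,
            neighbour_ratios={"gai": 0.9, "anl": 0.9},
        )
        assert out.gai_faws_ha == pytest.approx(4.5)
        assert out.uncertainty == 3

    def test_component_fill_from_neighbour_nai_gai_ratio(self):
        nai, anl = fill_components_from_ratio(5.0, 0.9)
        assert nai == pytest.approx(4.5)
        assert anl == pytest.approx(0.5)
        assert nai + anl == pytest.approx(5.0, abs=1e-12)

    def test_no_branch_applicable_rejected(self):
        with pytest.raises(ValueError, match="no gap-fill branch"):
            gapfill_increment(record_forest_only(), 1.4e6, 1.0e6)

    def test_both_categories_present_rejected(self):
        rec = IncrementStats(
            unit="AA1", ref_year=2015,
            gai_forest_ha=5.0, anl_forest_ha=0.5,
            gai_faws_ha=5.5, anl_faws_ha=0.5,
        )
        with pytest.raises(ValueError):
            gapfill_increment(rec, 1e6, 1e6)

    def test_identity_holds_on_scene_truth_with_hidden_category(self, small_scene):
        """Hiding FAWS on a unit whose areas are within 15% and gap-filling
        recovers it exactly; the additive identity holds throughout."""
        import math

        for code, row in small_scene.truth_increment.iterrows():
            af, aw = row["area_forest_ha"], row["area_faws_ha"]
            if af <= 0 or abs(af - aw) / max(af, aw) >= 0.15:
                continue
            rec = IncrementStats(
                unit=code, ref_year=2015,
                gai_forest_ha=row["gai_forest_m3_ha_yr"],
                anl_forest_ha=row["anl_forest_m3_ha_yr"],
            )
            out = gapfill_increment(rec, af, aw)
            assert out.gai_faws_ha == rec.gai_forest_ha
            assert out.gai_faws_ha == pytest.approx(
                out.nai_faws_ha + out.anl_faws_ha, abs=1e-9
            )
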