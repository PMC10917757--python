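"""Temporal adjustment and gap-filling of volume increment statistics.

Increments (gross annual increment GAI, natural losses ANL, net annual
increment NAI = GAI - ANL, all m3/ha/yr) are reported for a national
inventory period and brought to the 2015 reference year with a national
correction factor: the ratio of the reporting-database (SoEF) FAWS GAI in
2015 to its average over the inventory period. Natural losses are treated
as a stable fraction of the gross increment, so the corrected ANL keeps the
pre-correction ANL/GAI ratio and NAI follows by difference — the identity
GAI = NAI + ANL is preserved exactly.

When a country reports increment for only one category (total forest or
FAWS), the other is filled by a decision tree: copy the per-ha values when
the two areas are similar (<15% apart), otherwise scale by the SoEF
cross-category ratio, otherwise borrow the ratio from a configured
neighbouring country.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Tuple

from .core import (
    MISSING,
    GapfillScope,
    IncrementStats,
    SoefSeries,
    assign_uncertainty,
    is_missing,
)

__all__ = [
    "IncrementAdjustment",
    "temporal_adjust_increment",
    "totals_from_perha",
    "gapfill_increment",
    "fill_components_from_ratio",
    "DEFAULT_AREA_SIMILARITY",
]

log = logging.getLogger(__name__)

#: relative area difference below which forest and FAWS per-ha increments
#: are considered interchangeable
DEFAULT_AREA_SIMILARITY = 0.15

#: inventory periods inside this window are already representative of the
#: 2015 reference year and need no temporal adjustment
COVERED_PERIOD = (2010, 2020)


@dataclass(frozen=True)
class IncrementAdjustment:
    """Record of the temporal correction applied to a country's increment."""

    country: str
    correction_factor: float
    applied: bool
    anl_gai_ratio: float

    def __post_init__(self):
        if self.correction_factor <= 0:
            raise ValueError("correction factor must be positive")
        if not 0 <= self.anl_gai_ratio < 1:
            raise ValueError("ANL/GAI ratio must be in [0, 1)")


def temporal_adjust_increment(
    gai_ha: float,
    anl_ha: float,
    nfi_period: Tuple[int, int],
    soef: SoefSeries,
    ref_year: int = 2015,
    covered_period: Tuple[int, int] = COVERED_PERIOD,
) -> Tuple[float, float, float, IncrementAdjustment]:
    """Adjust per-ha increments from an inventory period to the reference year.

    Returns (gai', anl', nai', adjustment). No adjustment is applied when
    the inventory period already lies within the covered window (default
    2010-2020), whose data are taken as representative of mid-period 2015.
    The SoEF GAI series for FAWS is used for the correction factor because
    it is the more densely sampled and more reliably reported category; the
    average over the inventory period is a trapezoidal mean of the linearly
    interpolated series.
    """
    if gai_ha <= 0:
        raise ValueError("GAI must be positive")
    if not 0 <= anl_ha < gai_ha:
        raise ValueError("ANL must be in [0, GAI)")
    start, end = nfi_period
    if end < start:
        raise ValueError("inventory period end precedes start")

    ratio = anl_ha / gai_ha
    if covered_period[0] <= start and end <= covered_period[1]:
        adj = IncrementAdjustment(soef.country, 1.0, False, ratio)
        return gai_ha, anl_ha, gai_ha - anl_ha, adj

    gai_ref = soef.value_at("gai_faws_ha", ref_year)
    gai_period = soef.mean_over("gai_faws_ha", start, end)
    if gai_period <= 0:
        raise ValueError(
            f"{soef.country}: SoEF GAI not usable over {start}-{end}"
        )
    c = gai_ref / gai_period
    gai2 = gai_ha * c
    anl2 = gai2 * ratio
    adj = IncrementAdjustment(soef.country, c, True, ratio)
    return gai2, anl2, gai2 - anl2, adj


def totals_from_perha(per_ha: float, area: float) -> float:
    """Total increment (m3/yr) from a per-ha value and the category area
    reported for the reference year."""
    if area < 0:
        raise ValueError("area must be non-negative")
    if is_missing(per_ha):
        return MISSING
    return per_ha * area


def fill_components_from_ratio(
    gai_ha: float, nai_gai_ratio: float
) -> Tuple[float, float]:
    """Complete (NAI, ANL) from a GAI and a borrowed NAI/GAI ratio.

    Used when a country reports only the gross increment: the net increment
    is the gross times the NAI/GAI ratio of a similar (neighbouring)
    country, and the natural losses follow as the difference. The caller is
    responsible for labelling the result with uncertainty 3.
    """
    if gai_ha < 0:
        raise ValueError("GAI must be non-negative")
    if not 0 < nai_gai_ratio <= 1:
        raise ValueError("NAI/GAI ratio must be in (0, 1]")
    nai = gai_ha * nai_gai_ratio
    return nai, gai_ha - nai


def _soef_ratio(
    soef: SoefSeries, component: str, target_cat: str, ref_year: int
) -> Optional[float]:
    """SoEF per-ha ratio target/source for one component at national scale."""
    src_cat = "faws" if target_cat == "forest" else "forest"
    try:
        num = soef.value_at(f"{component}_{target_cat}_ha", ref_year)
        den = soef.value_at(f"{component}_{src_cat}_ha", ref_year)
    except ValueError:
        return None
    if den <= 0 or num < 0:
        return None
    return num / den


def gapfill_increment(
    record: IncrementStats,
    forest_area: float,
    faws_area: float,
    soef: Optional[SoefSeries] = None,
    neighbour_ratios: Optional[Mapping[str, float]] = None,
    area_similarity: float = DEFAULT_AREA_SIMILARITY,
    ref_year: int = 2015,
) -> IncrementStats:
    """Fill the missing increment category of a record.

    Decision tree: (1) if forest and FAWS areas differ by less than
    ``area_similarity`` the per-ha values are copied across categories
    (uncertainty 2); (2) else, if the SoEF series reports both categories,
    the missing one is obtained with the national SoEF cross-category
    per-ha ratio (uncertainty 2); (3) else the ratio of a configured
    neighbouring country is applied (uncertainty 3). Totals are recomputed
    from the correct category areas and GAI = NAI + ANL is preserved.

    ``neighbour_ratios`` maps component names ('gai', 'anl') to the donor's
    target/source per-ha ratios.
    """
    have_forest = record.has_category("forest")
    have_faws = record.has_category("faws")
    if have_forest == have_faws:
        raise ValueError("exactly one category must be present in the record")
    src, dst = ("forest", "faws") if have_forest else ("faws", "forest")

    if max(forest_area, faws_area) <= 0:
        raise ValueError("areas must be positive")
    rel_gap = abs(forest_area - faws_area) / max(forest_area, faws_area)

    gai_src = getattr(record, f"gai_{src}_ha")
    anl_src = getattr(record, f"anl_{src}_ha")

    if rel_gap < area_similarity:
        gai_dst, anl_dst = gai_src, anl_src
        scope = GapfillScope.SAME_COUNTRY
    else:
        r_gai = _soef_ratio(soef, "gai", dst, ref_year) if soef else None
        r_nai = _soef_ratio(soef, "nai", dst, ref_year) if soef else None
        if r_gai is not None and r_nai is not None:
            gai_dst = gai_src * r_gai
            nai_dst = (gai_src - anl_src) * r_nai
            anl_dst = max(gai_dst - nai_dst, 0.0)
            scope = GapfillScope.SAME_COUNTRY
        elif neighbour_ratios:
            if "gai" not in neighbour_ratios:
                raise ValueError("neighbour ratios must include 'gai'")
            gai_dst = gai_src * neighbour_ratios["gai"]
            anl_dst = anl_src * neighbour_ratios.get(
                "anl", neighbour_ratios["gai"]
            )
            scope = GapfillScope.OTHER_COUNTRY
        else:
            raise ValueError(
                f"{record.unit}: no gap-fill branch applicable (areas "
                f"{rel_gap:.0%} apart, no SoEF cross-category data, no "
                "neighbour configured)"
            )

    if gai_dst < anl_dst:
        anl_dst = gai_dst  # degenerate ratios: losses cannot exceed growth

    out = replace(
        record,
        area_forest=forest_area,
        area_faws=faws_area,
        uncertainty=max(
            record.uncertainty, assign_uncertainty(record.source, scope)
        ),
        **{
            f"gai_{dst}_ha": gai_dst,
            f"anl_{dst}_ha": anl_dst,
            f"nai_{dst}_ha": gai_dst - anl_dst,
        },
    )
    return out
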