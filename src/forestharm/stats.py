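"""Tabular harmonisation of inventory statistics to a common reference year.

The stages mirror the production workflow for national statistics:

* forest-area reconciliation between the inventory (NFI) figure and the
  national reporting series (SoEF), with the 2% negligible-difference rule;
* linear rescaling of sub-national areas to the reconciled national total;
* temporal updating of biomass density via the modelled (CBM) relative net
  change between the NFI year and 2020, plus afforestation / deforestation
  stock terms valued at young-stand and mean densities respectively;
* FAWS area and biomass updated proportionally to the total change;
* biomass available for wood supply derived from the growing-stock ratio
  when only volume shares are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import CbmDensities, SoefSeries

__all__ = [
    "AreaMode",
    "AreaDecision",
    "reconcile_forest_area",
    "rescale_subnational",
    "temporal_update_biomass",
    "area_change_biomass",
    "derive_baws_from_gsv",
    "temporal_update_faws",
]

log = logging.getLogger(__name__)

#: differences below this fraction of the NFI area are treated as negligible
DEFAULT_AREA_TOLERANCE = 0.02
#: differences above this fraction are reported as substantial (descriptive)
DEFAULT_AREA_FLAG = 0.05


class AreaMode(str, Enum):
    MATCH_SOEF = "match_soef"
    EXTEND_NFI = "extend_nfi"


@dataclass(frozen=True)
class AreaDecision:
    """Outcome of the NFI-vs-SoEF forest area reconciliation."""

    mode: AreaMode
    rel_diff: float          # |NFI - SoEF| / NFI at the comparison year
    years_elapsed: int
    annual_change: float     # ha/yr, SoEF linear trend
    compare_year: float
    flagged: bool = False    # rel_diff above the reporting band


def reconcile_forest_area(
    nfi_area: float,
    nfi_year: int,
    soef: SoefSeries,
    target_year: int,
    area_tolerance: float = DEFAULT_AREA_TOLERANCE,
    area_flag: float = DEFAULT_AREA_FLAG,
    interpolate: bool = True,
) -> Tuple[float, AreaDecision]:
    """Forest area at ``target_year`` given an NFI figure and a SoEF series.

    The NFI area is compared against the SoEF value closest in time to the
    NFI year (linearly interpolated between the bracketing reported years
    when ``interpolate`` is enabled; ties between reported years go to the
    earlier one). If the relative difference is within ``area_tolerance``
    (default 2%) the difference is considered negligible — an artefact of
    plot data being acquired over several years — and the SoEF area at the
    target year is adopted (*match_soef*). Otherwise the two sources use
    genuinely different forest definitions and the NFI area is extended to
    the target year by adding the SoEF annual area change times the elapsed
    years (*extend_nfi*).
    """
    if nfi_area <= 0:
        raise ValueError("NFI area must be positive")
    if target_year < nfi_year:
        raise ValueError("target year precedes NFI year")

    if interpolate:
        compare_year = float(nfi_year)
        soef_at_nfi = soef.value_at("forest_area", nfi_year)
    else:
        compare_year = soef.closest_year(nfi_year)
        soef_at_nfi = soef.value_at("forest_area", compare_year)

    rel_diff = abs(nfi_area - soef_at_nfi) / nfi_area
    annual_change = soef.trend("forest_area")
    years_elapsed = int(target_year - nfi_year)

    if rel_diff <= area_tolerance:
        area = soef.value_at("forest_area", target_year)
        mode = AreaMode.MATCH_SOEF
    else:
        area = nfi_area + annual_change * years_elapsed
        mode = AreaMode.EXTEND_NFI
        if rel_diff > area_flag:
            log.warning(
                "%s: NFI forest area differs from SoEF by %.1f%% (> %.0f%%)",
                soef.country, 100 * rel_diff, 100 * area_flag,
            )
    return area, AreaDecision(
        mode=mode,
        rel_diff=rel_diff,
        years_elapsed=years_elapsed,
        annual_change=annual_change,
        compare_year=compare_year,
        flagged=rel_diff > area_flag,
    )


def rescale_subnational(
    sub_areas: Sequence[float], national_total: float
) -> np.ndarray:
    """Linearly rescale sub-national values so their sum equals the national
    total (the relative distribution among units is preserved)."""
    sub = np.asarray(sub_areas, dtype=float)
    if np.any(sub < 0):
        raise ValueError("sub-national areas must be non-negative")
    s = sub.sum()
    if s <= 0:
        raise ValueError("sub-national areas sum to zero; cannot rescale")
    return sub * (national_total / s)


def temporal_update_biomass(d_nfi: float, cbm: CbmDensities) -> float:
    """Update a biomass density (t/ha) from the NFI year to 2020 using the
    modelled relative net change (growth, mortality, harvest) on stable
    forest land."""
    if d_nfi < 0:
        raise ValueError("density must be non-negative")
    out = d_nfi * cbm.change_factor
    if out < 0:
        raise ValueError("change factor drove density negative")
    return out


def soef_change_factor(soef: SoefSeries, nfi_year: int, target_year: int) -> float:
    """Fallback change factor from the SoEF biomass stock series, for
    countries without modelled densities: stock(target) / stock(NFI year)."""
    b0 = soef.value_at("agb", nfi_year)
    b1 = soef.value_at("agb", target_year)
    if b0 <= 0:
        raise ValueError(f"{soef.country}: non-positive SoEF biomass at {nfi_year}")
    return b1 / b0


def area_change_biomass(
    net_aff_area: float, net_def_area: float, d_young: float, d_mean: float
) -> float:
    """Signed biomass stock change (t) due to net forest area change.

    Afforested area is valued at the young-stand (age 0-19) density, the
    deforested area at the unit's mean forest density.
    """
    if min(net_aff_area, net_def_area) < 0:
        raise ValueError("areas must be non-negative")
    if min(d_young, d_mean) < 0:
        raise ValueError("densities must be non-negative")
    return net_aff_area * d_young - net_def_area * d_mean


def split_net_area_change(delta_area: float) -> Tuple[float, float]:
    """Interpret a signed net area change as (afforestation, deforestation)."""
    return (delta_area, 0.0) if delta_area >= 0 else (0.0, -delta_area)


def derive_baws_from_gsv(
    agb_stock: float, gsv_faws: float, gsv_total: float
) -> float:
    """Biomass available for wood supply (t) from the growing-stock share.

    Reporting databases give availability only as growing stock volume; the
    biomass share is taken proportional to the volume share.
    """
    if gsv_total <= 0:
        raise ValueError("total GSV must be positive")
    if not 0 <= gsv_faws <= gsv_total:
        raise ValueError("GSV available for wood supply outside [0, total]")
    if agb_stock < 0:
        raise ValueError("biomass stock must be non-negative")
    return agb_stock * gsv_faws / gsv_total


def temporal_update_faws(
    faws_value_nfi: float, total_nfi: float, total_target: float
) -> float:
    """Update a FAWS quantity (area or biomass) proportionally to the change
    in the corresponding total between the NFI year and the target year."""
    if total_nfi <= 0:
        raise ValueError("total at NFI year must be positive")
    if faws_value_nfi < 0 or total_target < 0:
        raise ValueError("values must be non-negative")
    return faws_value_nfi * total_target / total_nfi
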