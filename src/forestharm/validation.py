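"""Divergence metrics between maps and reference statistics.

The pipeline's maps are calibrated against the statistics, so their
residual divergence should reduce to the pixel-quantisation of area. The
relative Mean Absolute Error (rMAE) — the mean absolute per-zone difference
divided by the mean of the reference values — is the summary metric; the
biomass comparison is performed on stocks (t) rather than densities, so
zones are weighted by what they actually contain rather than each counting
equally regardless of their area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .raster import Grid, zonal_stats

__all__ = ["rmae", "ComparisonReport", "coherence_check"]


def rmae(map_values, ref_values) -> float:
    """Relative mean absolute error: mean(|map - ref|) / mean(ref).

    Inputs are paired per-zone vectors over the same zones.
    """
    m = np.asarray(map_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if m.shape != r.shape:
        raise ValueError("paired vectors must have the same length")
    if m.size == 0:
        raise ValueError("empty comparison")
    ref_mean = r.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(np.abs(m - r).mean() / ref_mean)


@dataclass
class ComparisonReport:
    """Per-quantity map-vs-statistics comparison of a pipeline run."""

    table: pd.DataFrame                    # zone, quantity, map, ref, abs_diff
    rmae_by_quantity: Dict[str, float]
    flagged: pd.DataFrame                  # zones exceeding tolerance
    shares: Dict[str, float] = field(default_factory=dict)

    def rmae_of(self, quantity: str) -> float:
        return self.rmae_by_quantity[quantity]


def _compare(
    name: str,
    per_zone_map: pd.Series,
    ref: Mapping[int, float],
    rows: list,
):
    zones = sorted(set(per_zone_map.index) & set(ref))
    for z in zones:
        rows.append(
            {
                "zone": int(z),
                "quantity": name,
                "map": float(per_zone_map.loc[z]),
                "ref": float(ref[z]),
                "abs_diff": abs(float(per_zone_map.loc[z]) - float(ref[z])),
            }
        )


def coherence_check(
    zone_map: Grid,
    forest_mask: Grid,
    agb_map: Grid,
    ref_area: Mapping[int, float],
    ref_stock: Mapping[int, float],
    faws_mask: Optional[Grid] = None,
    fnaws_mask: Optional[Grid] = None,
    ref_faws_area: Optional[Mapping[int, float]] = None,
    ref_baws_stock: Optional[Mapping[int, float]] = None,
    tolerance: float = 0.01,
) -> ComparisonReport:
    """Compare the pipeline's maps with their calibration statistics.

    Reports, per zone and per quantity, the mapped aggregate against the
    reference, plus the rMAE of: the forest-area map, the biomass map (as
    stock, t), and — when provided — the FAWS/FNAWS area and FAWS biomass
    stock. Zones whose relative difference exceeds ``tolerance`` are
    flagged.
    """
    rows: list = []

    area_stats = zonal_stats(forest_mask, zone_map, mask=forest_mask)
    _compare("forest_area_ha", area_stats["area_ha"], ref_area, rows)

    stock_stats = zonal_stats(agb_map, zone_map, mask=forest_mask)
    stock = stock_stats["sum"] * agb_map.pixel_area
    _compare("agb_stock_t", stock, ref_stock, rows)

    if faws_mask is not None and ref_faws_area is not None:
        fstats = zonal_stats(faws_mask, zone_map, mask=faws_mask)
        _compare("faws_area_ha", fstats["area_ha"], ref_faws_area, rows)
        if fnaws_mask is not None:
            nstats = zonal_stats(fnaws_mask, zone_map, mask=fnaws_mask)
            ref_fnaws = {
                z: ref_area[z] - ref_faws_area[z]
                for z in ref_faws_area
                if z in ref_area
            }
            _compare("fnaws_area_ha", nstats["area_ha"], ref_fnaws, rows)
    if faws_mask is not None and ref_baws_stock is not None:
        bstats = zonal_stats(agb_map, zone_map, mask=faws_mask)
        baws = bstats["sum"] * agb_map.pixel_area
        _compare("baws_stock_t", baws, ref_baws_stock, rows)

    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("nothing to compare; missing pipeline outputs")

    rmae_by_quantity = {
        q: rmae(sub["map"].to_numpy(), sub["ref"].to_numpy())
        for q, sub in table.groupby("quantity")
    }
    rel = table["abs_diff"] / table["ref"].where(table["ref"] > 0, np.nan)
    flagged = table[rel > tolerance].copy()

    shares: Dict[str, float] = {}
    if faws_mask is not None and ref_faws_area is not None:
        zones = sorted(set(ref_area) & set(ref_faws_area))
        tot = sum(ref_area[z] for z in zones)
        if tot > 0:
            shares["faws_area_share_stats"] = (
                sum(ref_faws_area[z] for z in zones) / tot
            )
        fstats = zonal_stats(faws_mask, zone_map, mask=faws_mask)
        astats = zonal_stats(forest_mask, zone_map, mask=forest_mask)
        if astats["area_ha"].sum() > 0:
            shares["faws_area_share_map"] = (
                fstats["area_ha"].sum() / astats["area_ha"].sum()
            )

    return ComparisonReport(
        table=table,
        rmae_by_quantity=rmae_by_quantity,
        flagged=flagged,
        shares=shares,
    )
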