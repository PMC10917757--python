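"""Biomass raster correction: zero-biomass infill and zonal bias adjustment.

Satellite biomass maps carry a systematic component of error that can be
removed against reference statistics, and occasionally contain forested
zones reported as zero biomass that would inflate the correction factors.
The workflow is: mask to the reference forest area, estimate biomass in the
zero-valued forest pixels from the local tree-cover relation, then multiply
each reporting unit by the ratio of the reference density to the map's mean
density over the same area, so the adjusted map reproduces the reference
statistics exactly at the unit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .raster import Grid, require_coregistered, zonal_stats

__all__ = [
    "CoverBiomassModel",
    "fit_cover_model",
    "infill_zero_biomass",
    "bias_adjust_map",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_PIXELS = 100


@dataclass(frozen=True)
class CoverBiomassModel:
    """Local linear relation between tree cover (%) and biomass (t/ha).

    Fitted by ordinary least squares on forest pixels with positive biomass
    inside the calibration region only; the relation saturates with canopy
    closure, so it is meant for local application, not continental transfer.
    """

    intercept: float             # t/ha
    slope: float                 # t/ha per % cover
    calibration_region: FrozenSet[int]
    n_pixels: int
    r2: float

    def predict(self, cover: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(cover, dtype=float)


def _region_mask(zone_map: Grid, region: Iterable[int]) -> np.ndarray:
    return np.isin(np.asarray(zone_map.values), list(region))


def fit_cover_model(
    biomass: Grid,
    tree_cover: Grid,
    forest_mask: Grid,
    zone_map: Grid,
    region: Iterable[int],
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> CoverBiomassModel:
    """OLS fit of biomass on tree cover over a calibration region.

    Eligible pixels are forest, inside the region, with valid biomass > 0
    (zero-biomass pixels are the ones to be predicted, so they are excluded
    from the fit).
    """
    require_coregistered(biomass, tree_cover, forest_mask, zone_map)
    region = frozenset(int(z) for z in region)
    eligible = (
        _region_mask(zone_map, region)
        & (np.asarray(forest_mask.values) != 0)
        & biomass.valid()
        & (np.asarray(biomass.values, dtype=float) > 0)
        & tree_cover.valid()
    )
    n = int(eligible.sum())
    if n < min_pixels:
        raise ValueError(
            f"only {n} eligible pixels in region (minimum {min_pixels})"
        )
    x = np.asarray(tree_cover.values, dtype=float)[eligible]
    y = np.asarray(biomass.values, dtype=float)[eligible]
    if np.ptp(x) == 0:
        raise ValueError("tree cover has zero variance in the region")
    res = sps.linregress(x, y)
    return CoverBiomassModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        calibration_region=region,
        n_pixels=n,
        r2=float(res.rvalue**2),
    )


def infill_zero_biomass(
    biomass: Grid,
    model: CoverBiomassModel,
    forest_mask: Grid,
    tree_cover: Grid,
    zone_map: Grid,
    region: Iterable[int],
    nodata_as_zero: bool = True,
) -> Grid:
    """Predict biomass for zero-valued forest pixels of the model's region.

    Only pixels that are forest, inside the calibration region, and carry
    zero biomass (or nodata, when ``nodata_as_zero``) are replaced by the
    model prediction, floored at 0 and capped at the region's observed
    maximum; every other pixel is bit-identical to the input.
    """
    require_coregistered(biomass, forest_mask, tree_cover, zone_map)
    region = frozenset(int(z) for z in region)
    if region != model.calibration_region:
        raise ValueError(
            "infill region does not match the model's calibration region"
        )
    in_region = _region_mask(zone_map, region)
    forest = np.asarray(forest_mask.values) != 0
    vals = np.asarray(biomass.values, dtype=float)
    zeroish = biomass.valid() & (vals == 0)
    if nodata_as_zero:
        zeroish |= ~biomass.valid()
    target = in_region & forest & zeroish

    observed = in_region & forest & biomass.valid() & (vals > 0)
    cap = float(vals[observed].max()) if observed.any() else np.inf

    out = vals.copy()
    pred = model.predict(np.asarray(tree_cover.values, dtype=float)[target])
    out[target] = np.clip(pred, 0.0, cap)
    return biomass.like(out)


def bias_adjust_map(
    biomass: Grid,
    zone_map: Grid,
    forest_mask: Grid,
    ref_density: Mapping[int, float],
    factor_clamp: Optional[Tuple[float, float]] = None,
) -> Tuple[Grid, pd.DataFrame]:
    """Per-zone multiplicative bias adjustment of a biomass map.

    For each reporting zone, the correction factor is the ratio between the
    reference biomass density (t/ha) and the mean of the map over the forest
    pixels of that zone; every forest pixel of the zone is multiplied by it,
    so the adjusted zonal mean equals the reference exactly. Zones without a
    reference pass through with a warning; zones whose map mean is zero but
    whose reference is positive cannot be scaled and are flagged.

    ``factor_clamp`` optionally bounds the factors (pathological zones); a
    clamped zone no longer reproduces its reference exactly and is flagged.
    """
    require_coregistered(biomass, zone_map, forest_mask)
    zs = zonal_stats(biomass, zone_map, mask=forest_mask)

    out = np.asarray(biomass.values, dtype=float).copy()
    zones = np.asarray(zone_map.values)
    forest = np.asarray(forest_mask.values) != 0

    records = []
    for zid in zs.index:
        row = zs.loc[zid]
        ref = ref_density.get(int(zid))
        rec = {
            "zone": int(zid),
            "map_mean": row["mean"],
            "ref_density": np.nan if ref is None else float(ref),
            "factor": np.nan,
            "flag": "",
        }
        if ref is None:
            log.warning("zone %d: no reference density; passthrough", zid)
            rec["flag"] = "no_reference"
        elif row["count"] == 0 or not np.isfinite(row["mean"]):
            rec["flag"] = "empty_zone"
        elif row["mean"] <= 0:
            if ref > 0:
                log.warning("zone %d: zero map mean, positive reference", zid)
                rec["flag"] = "zero_mean"
        else:
            factor = float(ref) / float(row["mean"])
            if factor_clamp is not None:
                lo, hi = factor_clamp
                clamped = min(max(factor, lo), hi)
                if clamped != factor:
                    rec["flag"] = "clamped"
                factor = clamped
            rec["factor"] = factor
            sel = forest & (zones == zid)
            out[sel] *= factor
        records.append(rec)

    return biomass.like(out), pd.DataFrame(records).set_index("zone")
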