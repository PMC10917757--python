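"""Wood-supply restriction layers, threshold calibration and FAWS masks.

Six mappable restrictions limit wood availability: steep slope, high
altitude, protected areas, protected species, poor accessibility (distance
to roads) and low productivity (kNDVI). For each restriction and country the
threshold is not prescribed but *calibrated*: it is set to the value that,
applied to the restriction layer over the country's forest, restricts an
area matching the reference statistic for that restriction. The forest not
available for wood supply (FNAWS) is the union of the calibrated restricted
sets, and FAWS is its complement within the forest mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .raster import Grid, require_coregistered

__all__ = [
    "Direction",
    "RestrictionRule",
    "compute_kndvi",
    "calibrate_threshold",
    "restricted_mask",
    "build_fnaws_mask",
    "faws_biomass_map",
    "inherit_thresholds",
    "RESTRICTION_DIRECTIONS",
    "DEFAULT_THRESHOLD_PRIORS",
]

log = logging.getLogger(__name__)

#: sentinel thresholds: restrict nothing / restrict everything
RESTRICT_NONE = float("inf")
RESTRICT_ALL = float("-inf")


class Direction(str, Enum):
    ABOVE = "restricted_above"   # value > threshold is restricted
    BELOW = "restricted_below"   # value <= threshold is restricted
    EQUAL = "restricted_equal"   # value == threshold is restricted (binary)


#: fixed direction per restriction: slope/altitude/distance restrict above,
#: productivity restricts below, protected layers restrict a class.
RESTRICTION_DIRECTIONS: Dict[str, Direction] = {
    "slope": Direction.ABOVE,
    "altitude": Direction.ABOVE,
    "accessibility": Direction.ABOVE,
    "productivity": Direction.BELOW,
    "protected_area": Direction.EQUAL,
    "protected_species": Direction.EQUAL,
}

#: typical calibrated values, usable as priors when no statistics constrain a
#: run: ~30 deg slope, 2000 m altitude, ~1000 m to the nearest road,
#: kNDVI 0.1-0.2 for unproductive forest, class 1 for the binary layers.
DEFAULT_THRESHOLD_PRIORS: Dict[str, float] = {
    "slope": 30.0,
    "altitude": 2000.0,
    "accessibility": 1000.0,
    "productivity": 0.15,
    "protected_area": 1.0,
    "protected_species": 1.0,
}


def compute_kndvi(nir: Grid, red: Grid, sigma: float = 0.15) -> Grid:
    """Kernel NDVI productivity index.

    kNDVI = tanh( ((NIR - RED) / (2 sigma))^2 ), bounded in [0, 1). The
    kernel length-scale ``sigma`` defaults to 0.15 reflectance units, the
    value adopted for continental productivity mapping.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    require_coregistered(nir, red)
    n = np.asarray(nir.values, dtype=float)
    r = np.asarray(red.values, dtype=float)
    if np.nanmin(n) < 0 or np.nanmax(n) > 1 or np.nanmin(r) < 0 or np.nanmax(r) > 1:
        raise ValueError("reflectances must lie in [0, 1]")
    return nir.like(np.tanh(((n - r) / (2.0 * sigma)) ** 2))


@dataclass
class RestrictionRule:
    """One restriction layer with its per-region calibrated thresholds.

    ``calibration_regions`` is an optional region-id grid partitioning a
    country (e.g. a north/south split along a strong ecological gradient);
    when absent the whole domain is a single region 0. ``exclude`` names
    rules whose restricted pixels are removed from this rule's calibration
    pool, to avoid double counting a restriction nested inside another.
    """

    name: str
    grid: Grid
    direction: Direction = None  # type: ignore[assignment]
    calibration_regions: Optional[Grid] = None
    thresholds: Dict[int, float] = field(default_factory=dict)
    provenance: str = "calibrated"
    uncertainty: int = 0
    exclude: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.direction is None:
            if self.name not in RESTRICTION_DIRECTIONS:
                raise ValueError(
                    f"unknown restriction {self.name!r}; give a direction"
                )
            self.direction = RESTRICTION_DIRECTIONS[self.name]
        self.direction = Direction(self.direction)

    def region_ids(self) -> List[int]:
        if self.calibration_regions is None:
            return [0]
        regs = np.asarray(self.calibration_regions.values)
        return sorted(int(r) for r in np.unique(regs[regs >= 0]))

    def region_mask(self, region: int) -> Optional[np.ndarray]:
        if self.calibration_regions is None:
            return None
        return np.asarray(self.calibration_regions.values) == region


def _restricted_count(values: np.ndarray, t: float, direction: Direction) -> int:
    if direction is Direction.ABOVE:
        return int(np.count_nonzero(values > t))
    if direction is Direction.BELOW:
        return int(np.count_nonzero(values <= t))
    return int(np.count_nonzero(values == t))


def _best_threshold(
    values: np.ndarray, n_target: float, direction: Direction
) -> Tuple[float, int]:
    """Exact search over the sorted unique values for the threshold whose
    restricted count is closest to the target; ties restrict the smaller
    area. Equivalent to reading off a quantile of the forest-pixel values."""
    v = np.sort(values)
    uniq = np.unique(v)
    n = v.size
    if direction is Direction.ABOVE:
        # candidates: each unique value (strictly-above rule) plus -inf
        counts = n - np.searchsorted(v, uniq, side="right")
        cand = np.concatenate((uniq, [RESTRICT_ALL]))
        counts = np.concatenate((counts, [n]))
    elif direction is Direction.BELOW:
        # candidates: each unique value (inclusive-below rule) plus -inf
        counts = np.searchsorted(v, uniq, side="right")
        cand = np.concatenate((uniq, [RESTRICT_ALL]))
        counts = np.concatenate((counts, [0]))
    else:
        counts = np.array([np.count_nonzero(v == u) for u in uniq])
        cand = uniq
    err = np.abs(counts - n_target)
    best = err.min()
    ties = np.flatnonzero(err == best)
    pick = ties[np.argmin(counts[ties])]
    return float(cand[pick]), int(counts[pick])


def calibrate_threshold(
    rule: RestrictionRule,
    forest_mask: Grid,
    target_area: Mapping[int, float] | float,
    already_restricted: Optional[np.ndarray] = None,
) -> Dict[int, float]:
    """Set the rule's thresholds so each region's restricted forest area
    matches its target.

    ``target_area`` is hectares per region id (a scalar is accepted for the
    single-region case). The search is exact over the unique forest-pixel
    values of the rule layer; the achieved area is within one pixel of the
    best attainable. A zero target yields a sentinel restricting nothing; a
    target equal to the full forest area a sentinel restricting everything.
    ``already_restricted`` (boolean array) removes pixels claimed by rules
    named in ``rule.exclude`` from the calibration pool.
    """
    require_coregistered(rule.grid, forest_mask)
    if not isinstance(target_area, Mapping):
        target_area = {0: float(target_area)}

    forest = (np.asarray(forest_mask.values) != 0) & rule.grid.valid()
    if already_restricted is not None:
        forest = forest & ~already_restricted
    pa = forest_mask.pixel_area
    vals_all = np.asarray(rule.grid.values, dtype=float)

    thresholds: Dict[int, float] = {}
    for region, target in sorted(target_area.items()):
        rmask = rule.region_mask(region)
        sel = forest if rmask is None else (forest & rmask)
        values = vals_all[sel]
        n = values.size
        if target < 0 or target > n * pa + pa:
            raise ValueError(
                f"{rule.name}/region {region}: target {target} ha exceeds "
                f"forest area {n * pa} ha"
            )
        n_target = target / pa
        if n_target <= 0:
            thresholds[region] = (
                RESTRICT_NONE if rule.direction is not Direction.BELOW
                else RESTRICT_ALL
            )
            continue
        if n == 0:
            raise ValueError(
                f"{rule.name}/region {region}: positive target but no forest"
            )
        if round(n_target) >= n and rule.direction is not Direction.EQUAL:
            thresholds[region] = (
                RESTRICT_ALL if rule.direction is not Direction.BELOW
                else float(values.max())
            )
            continue
        t, _count = _best_threshold(values, n_target, rule.direction)
        thresholds[region] = t
    rule.thresholds = thresholds
    return thresholds


def restricted_mask(rule: RestrictionRule, forest_mask: Grid) -> Grid:
    """Boolean grid of forest pixels restricted by a calibrated rule."""
    if not rule.thresholds:
        raise ValueError(f"rule {rule.name} has no calibrated thresholds")
    require_coregistered(rule.grid, forest_mask)
    forest = (np.asarray(forest_mask.values) != 0) & rule.grid.valid()
    vals = np.asarray(rule.grid.values, dtype=float)
    out = np.zeros(vals.shape, dtype=bool)
    for region, t in rule.thresholds.items():
        rmask = rule.region_mask(region)
        sel = forest if rmask is None else (forest & rmask)
        if rule.direction is Direction.ABOVE:
            hit = vals > t
        elif rule.direction is Direction.BELOW:
            hit = vals <= t
        else:
            hit = vals == t
        out |= sel & hit
    return forest_mask.like(out.astype(np.uint8), nodata=255)


def build_fnaws_mask(
    rules: Iterable[RestrictionRule], forest_mask: Grid
) -> Tuple[Grid, Grid]:
    """FNAWS mask (union of restricted sets) and FAWS mask (its complement
    within the forest). The two partition the forest mask exactly."""
    forest = np.asarray(forest_mask.values) != 0
    fnaws = np.zeros(forest.shape, dtype=bool)
    for rule in rules:
        fnaws |= np.asarray(restricted_mask(rule, forest_mask).values) != 0
    faws = forest & ~fnaws
    return (
        forest_mask.like(fnaws.astype(np.uint8), nodata=255),
        forest_mask.like(faws.astype(np.uint8), nodata=255),
    )


def faws_biomass_map(agb_adjusted: Grid, faws_mask: Grid) -> Grid:
    """Bias-adjusted biomass retained on FAWS pixels, nodata elsewhere."""
    require_coregistered(agb_adjusted, faws_mask)
    out = np.asarray(agb_adjusted.values, dtype=float).copy()
    out[np.asarray(faws_mask.values) == 0] = np.nan
    return agb_adjusted.like(out, nodata=np.nan)


def inherit_thresholds(
    country: str,
    neighbour_map: Mapping[str, Iterable[str]],
    calibrated: Mapping[str, Mapping[str, Mapping[int, float]]],
) -> Tuple[Dict[str, Dict[int, float]], pd.DataFrame]:
    """Thresholds for a country without restriction statistics, taken from
    its configured donor countries with similar forestry conditions.

    A single donor's thresholds are copied; multiple donors are averaged
    per rule and region. The provenance table labels every inherited value
    with uncertainty 3 (extrapolated from other countries).
    """
    donors = [d for d in neighbour_map.get(country, []) if d in calibrated]
    if not donors:
        raise ValueError(f"{country}: no calibrated donor country available")
    rules = sorted({r for d in donors for r in calibrated[d]})
    out: Dict[str, Dict[int, float]] = {}
    rows = []
    for rule in rules:
        per_region: Dict[int, List[float]] = {}
        for d in donors:
            for region, t in calibrated[d].get(rule, {}).items():
                per_region.setdefault(region, []).append(t)
        out[rule] = {
            region: float(np.mean(ts)) for region, ts in per_region.items()
        }
        for region, t in out[rule].items():
            rows.append(
                {
                    "country": country,
                    "rule": rule,
                    "region": region,
                    "threshold": t,
                    "provenance": "neighbour:" + "+".join(donors),
                    "uncertainty": 3,
                }
            )
    return out, pd.DataFrame(rows)
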