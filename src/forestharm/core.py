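"""Shared domain types, unit conventions and the uncertainty-labelling rule.

Units are fixed package-wide: areas in hectares (ha), aboveground dry biomass
(AGB) in tonnes (t), carbon in tonnes of carbon (tC), growing stock volume in
cubic metres (m3), volume increment in m3/ha/yr (per-hectare) and m3/yr
(totals). Densities (t/ha) are stored alongside totals and reconciled so that
``density * area == stock`` always holds.

Missing numeric values are represented by NaN — an explicit sentinel distinct
from zero, because gap-filling logic branches on missingness while a zero
biomass stock is a legal value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Source",
    "GapfillScope",
    "AdminUnit",
    "ForestStats",
    "IncrementStats",
    "SoefSeries",
    "CbmDensities",
    "assign_uncertainty",
    "carbon_to_biomass",
    "is_missing",
    "MISSING",
]

#: sentinel for a value that is absent (distinct from zero).
MISSING = float("nan")

_REL_TOL = 1e-9


def is_missing(x) -> bool:
    """True when ``x`` is the missing-value sentinel (NaN or None)."""
    return x is None or (isinstance(x, float) and math.isnan(x)) or (
        isinstance(x, np.floating) and np.isnan(x)
    )


class Source(str, Enum):
    """Provenance of a statistic."""

    NFI = "NFI"      # harmonised national forest inventory
    SOEF = "SoEF"    # State of Europe's Forests national series
    CBM = "CBM"      # carbon budget model output
    GF = "GF"        # fully gap-filled

    @classmethod
    def coerce(cls, value) -> "Source":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value or member.name == str(value).upper():
                return member
        raise ValueError(f"unknown source {value!r}")


class GapfillScope(str, Enum):
    """Where the data used to fill a gap came from."""

    NONE = "none"
    SAME_COUNTRY = "same_country"
    OTHER_COUNTRY = "other_country"

    @classmethod
    def coerce(cls, value) -> "GapfillScope":
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        raise ValueError(f"unknown gap-fill scope {value!r}")


def assign_uncertainty(source, gapfill_scope="none", cbm_label: int = 1) -> int:
    """Uncertainty label 0-3 for a statistic given its provenance.

    0: harmonised NFI data (lowest uncertainty); 1: values derived from the
    SoEF database or CBM model; 2: missing values predicted from data of the
    same country; 3: missing values extrapolated from other countries.

    ``cbm_label`` configures the label of CBM-derived values (default 1: CBM
    is listed alongside SoEF as a modelled national source).
    """
    src = Source.coerce(source)
    scope = GapfillScope.coerce(gapfill_scope)
    if scope is GapfillScope.SAME_COUNTRY:
        return 2
    if scope is GapfillScope.OTHER_COUNTRY:
        return 3
    if src is Source.NFI:
        return 0
    if src is Source.SOEF:
        return 1
    if src is Source.CBM:
        if cbm_label not in (1, 2):
            raise ValueError("cbm_label must be 1 or 2")
        return cbm_label
    # a fully gap-filled record without scope information is maximally uncertain
    return 3


def carbon_to_biomass(carbon_stock: float, carbon_fraction: float = 0.5) -> float:
    """Convert a carbon stock (tC) to dry biomass (t).

    ``carbon_fraction`` is the carbon fraction of dry biomass; 0.5 is the
    conventional default used when a country does not report its own value.
    """
    if not 0.0 < carbon_fraction <= 1.0:
        raise ValueError(f"carbon fraction must be in (0, 1], got {carbon_fraction}")
    if carbon_stock < 0:
        raise ValueError("carbon stock must be non-negative")
    return carbon_stock / carbon_fraction


@dataclass(frozen=True)
class AdminUnit:
    """A NUTS-like administrative reporting unit.

    Level 0 is the country; levels 1-3 nest strictly (a level-k unit's parent
    has level k-1). Codes are unique within a hierarchy.
    """

    code: str
    level: int
    parent: Optional[str] = None
    country: Optional[str] = None

    def __post_init__(self):
        if not 0 <= self.level <= 3:
            raise ValueError(f"level must be 0-3, got {self.level}")
        if self.level == 0 and self.parent is not None:
            raise ValueError("level-0 units have no parent")
        if self.level > 0 and self.parent is None:
            raise ValueError(f"level-{self.level} unit {self.code} needs a parent")
        if self.country is None:
            object.__setattr__(self, "country", self.code[:2])


def validate_hierarchy(units: Sequence[AdminUnit]) -> None:
    """Check code uniqueness and parent-level consistency of a unit list."""
    by_code = {}
    for u in units:
        if u.code in by_code:
            raise ValueError(f"duplicate unit code {u.code}")
        by_code[u.code] = u
    for u in units:
        if u.parent is not None:
            parent = by_code.get(u.parent)
            if parent is None:
                raise ValueError(f"{u.code}: parent {u.parent} not in hierarchy")
            if parent.level != u.level - 1:
                raise ValueError(
                    f"{u.code} (level {u.level}): parent {u.parent} has level "
                    f"{parent.level}, expected {u.level - 1}"
                )


def _close(a: float, b: float, rel: float = _REL_TOL) -> bool:
    return abs(a - b) <= rel * max(abs(a), abs(b), 1e-300)


@dataclass
class ForestStats:
    """Per-unit forest area / biomass record for one reference year.

    Derived fields (``fnaws_area``, ``agb_density``, ``bnaws_stock``) are
    computed from the primary ones when left missing, and validated against
    them when given.
    """

    unit: str
    ref_year: int
    forest_area: float            # ha
    agb_stock: float              # t
    faws_area: float = MISSING    # ha
    baws_stock: float = MISSING   # t
    fnaws_area: float = MISSING   # ha
    bnaws_stock: float = MISSING  # t
    agb_density: float = MISSING  # t/ha
    source: Source = Source.NFI
    uncertainty: int = 0

    def __post_init__(self):
        self.source = Source.coerce(self.source)
        if self.uncertainty not in (0, 1, 2, 3):
            raise ValueError(f"uncertainty must be 0-3, got {self.uncertainty}")
        if self.forest_area < 0 or self.agb_stock < 0:
            raise ValueError("areas and stocks must be non-negative")
        if is_missing(self.agb_density):
            self.agb_density = (
                self.agb_stock / self.forest_area if self.forest_area > 0 else 0.0
            )
        elif self.forest_area > 0 and not _close(
            self.agb_density * self.forest_area, self.agb_stock, 1e-6
        ):
            raise ValueError(
                f"{self.unit}: density*area = {self.agb_density * self.forest_area} "
                f"inconsistent with stock {self.agb_stock}"
            )
        if not is_missing(self.faws_area):
            if self.faws_area < 0 or self.faws_area > self.forest_area * (1 + _REL_TOL):
                raise ValueError(f"{self.unit}: FAWS area outside [0, forest area]")
            if is_missing(self.fnaws_area):
                self.fnaws_area = self.forest_area - self.faws_area
            elif not _close(self.fnaws_area, self.forest_area - self.faws_area, 1e-6):
                raise ValueError(f"{self.unit}: FNAWS != forest - FAWS")
        if not is_missing(self.baws_stock):
            if self.baws_stock < 0 or self.baws_stock > self.agb_stock * (1 + _REL_TOL):
                raise ValueError(f"{self.unit}: BAWS outside [0, AGB stock]")
            if is_missing(self.bnaws_stock):
                self.bnaws_stock = self.agb_stock - self.baws_stock
            elif not _close(self.bnaws_stock, self.agb_stock - self.baws_stock, 1e-6):
                raise ValueError(f"{self.unit}: BNAWS != AGB - BAWS")

    def relabel(self, gapfill_scope="none") -> "ForestStats":
        return replace(
            self, uncertainty=assign_uncertainty(self.source, gapfill_scope)
        )


_CATEGORIES = ("forest", "faws")


@dataclass
class IncrementStats:
    """Per-unit volume increment record (gross, net, natural losses).

    For each category (total forest, FAWS) the gross annual increment (GAI)
    equals the net annual increment (NAI) plus the annual natural losses
    (ANL); totals are per-ha values times the category area.
    """

    unit: str
    ref_year: int
    # per-ha m3/ha/yr and areas (ha), by category
    gai_forest_ha: float = MISSING
    anl_forest_ha: float = MISSING
    nai_forest_ha: float = MISSING
    gai_faws_ha: float = MISSING
    anl_faws_ha: float = MISSING
    nai_faws_ha: float = MISSING
    area_forest: float = MISSING
    area_faws: float = MISSING
    source: Source = Source.NFI
    uncertainty: int = 0

    def __post_init__(self):
        self.source = Source.coerce(self.source)
        if self.uncertainty not in (0, 1, 2, 3):
            raise ValueError(f"uncertainty must be 0-3, got {self.uncertainty}")
        for cat in _CATEGORIES:
            gai, anl, nai = (
                getattr(self, f"gai_{cat}_ha"),
                getattr(self, f"anl_{cat}_ha"),
                getattr(self, f"nai_{cat}_ha"),
            )
            present = [v for v in (gai, anl, nai) if not is_missing(v)]
            if any(v < 0 for v in present):
                raise ValueError(f"{self.unit}: negative increment for {cat}")
            if len(present) == 3 and abs(gai - (nai + anl)) > 1e-9 * max(gai, 1e-300):
                raise ValueError(
                    f"{self.unit}: GAI != NAI + ANL for {cat} "
                    f"({gai} vs {nai} + {anl})"
                )
            # complete the triple when exactly one component is missing
            if len(present) == 2:
                if is_missing(nai):
                    setattr(self, f"nai_{cat}_ha", gai - anl)
                elif is_missing(anl):
                    setattr(self, f"anl_{cat}_ha", gai - nai)
                elif is_missing(gai):
                    setattr(self, f"gai_{cat}_ha", nai + anl)

    def has_category(self, cat: str) -> bool:
        return not is_missing(getattr(self, f"gai_{cat}_ha"))

    def total(self, component: str, cat: str) -> float:
        """Total increment (m3/yr) = per-ha value x category area."""
        per_ha = getattr(self, f"{component}_{cat}_ha")
        area = getattr(self, f"area_{cat}")
        if is_missing(per_ha) or is_missing(area):
            return MISSING
        return per_ha * area


@dataclass
class SoefSeries:
    """National time series in the style of the SoEF reporting database.

    Years are typically 1990-2020 in 5-year steps (2015 included). Quantities
    per year: forest / FAWS area (ha), AGB stock (t) or AGB carbon (tC) with a
    carbon fraction, growing stock volume total and available for wood supply
    (m3), and mean increments (m3/ha/yr) per category. Any per-year array may
    be absent (None). When both carbon and biomass are present, biomass wins;
    carbon is converted only if biomass is absent.
    """

    country: str
    years: np.ndarray
    forest_area: Optional[np.ndarray] = None
    faws_area: Optional[np.ndarray] = None
    agb: Optional[np.ndarray] = None
    agb_carbon: Optional[np.ndarray] = None
    carbon_fraction: float = 0.5
    gsv: Optional[np.ndarray] = None
    gsv_faws: Optional[np.ndarray] = None
    gai_forest_ha: Optional[np.ndarray] = None
    nai_forest_ha: Optional[np.ndarray] = None
    gai_faws_ha: Optional[np.ndarray] = None
    nai_faws_ha: Optional[np.ndarray] = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        if self.years.size == 0:
            raise ValueError("empty SoEF series")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        for name in (
            "forest_area", "faws_area", "agb", "agb_carbon", "gsv", "gsv_faws",
            "gai_forest_ha", "nai_forest_ha", "gai_faws_ha", "nai_faws_ha",
        ):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.years.shape:
                    raise ValueError(f"{name} length does not match years")
                if np.nanmin(arr) < 0:
                    raise ValueError(f"{name} has negative values")
                setattr(self, name, arr)
        if self.gsv is not None and self.gsv_faws is not None:
            if np.any(self.gsv_faws > self.gsv * (1 + _REL_TOL)):
                raise ValueError("gsv_faws exceeds gsv")

    def biomass_series(self) -> np.ndarray:
        """AGB stock series (t); converted from carbon when biomass absent."""
        if self.agb is not None:
            return self.agb
        if self.agb_carbon is not None:
            return self.agb_carbon / self.carbon_fraction
        raise ValueError(f"{self.country}: no biomass or carbon series")

    def _series(self, name: str) -> np.ndarray:
        if name == "agb":
            return self.biomass_series()
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{self.country}: series {name!r} not reported")
        return arr

    def value_at(self, name: str, year: float, extrapolate: bool = True) -> float:
        """Linearly interpolated value; outside the span, extended along the
        least-squares trend when ``extrapolate`` is true."""
        arr = self._series(name)
        ok = ~np.isnan(arr)
        if ok.sum() == 0:
            raise ValueError(f"{self.country}: series {name!r} all missing")
        yrs, vals = self.years[ok], arr[ok]
        if yrs[0] <= year <= yrs[-1]:
            return float(np.interp(year, yrs, vals))
        if not extrapolate:
            raise ValueError(f"{self.country}: year {year} outside series span")
        slope = self.trend(name)
        if year < yrs[0]:
            return float(vals[0] + slope * (year - yrs[0]))
        return float(vals[-1] + slope * (year - yrs[-1]))

    def trend(self, name: str) -> float:
        """Least-squares linear trend (units/yr) over the reported span."""
        arr = self._series(name)
        ok = ~np.isnan(arr)
        yrs, vals = self.years[ok], arr[ok]
        if yrs.size < 2:
            return 0.0
        return float(np.polyfit(yrs, vals, 1)[0])

    def closest_year(self, year: float) -> float:
        """Reported year closest to ``year``; ties go to the earlier year."""
        d = np.abs(self.years - year)
        # stable argmin returns the first (earlier) year on ties
        return float(self.years[int(np.argmin(d))])

    def mean_over(self, name: str, start: float, end: float) -> float:
        """Trapezoidal average of the interpolated series over [start, end]."""
        if end < start:
            raise ValueError("end before start")
        if end == start:
            return self.value_at(name, start)
        knots = self.years[(self.years > start) & (self.years < end)]
        grid = np.concatenate(([start], knots, [end]))
        vals = np.array([self.value_at(name, y) for y in grid])
        return float(np.trapezoid(vals, grid) / (end - start))


@dataclass(frozen=True)
class CbmDensities:
    """Modelled biomass densities (t/ha) used for temporal updating.

    ``d_nfi_year`` and ``d_2020`` give the modelled density at the inventory
    year and the 2020 reference year; ``d_young`` is the density of the young
    (age 0-19) stands used to value net afforestation.
    """

    code: str
    d_nfi_year: float
    d_2020: float
    d_young: float

    def __post_init__(self):
        if min(self.d_nfi_year, self.d_2020, self.d_young) <= 0:
            raise ValueError("CBM densities must be positive")

    @property
    def change_factor(self) -> float:
        """1 + relative net biomass change between the NFI year and 2020."""
        return 1.0 + (self.d_2020 - self.d_nfi_year) / self.d_nfi_year


# CSV layout shared by the table readers/writers (mirrors the published
# statistics tables: one row per unit, totals plus per-ha values).
FOREST_STATS_COLUMNS = [
    "unit", "level", "ref_year", "forest_area_ha", "faws_area_ha",
    "fnaws_area_ha", "agb_t", "agb_t_ha", "baws_t", "bnaws_t", "source",
    "uncertainty",
]

INCREMENT_STATS_COLUMNS = [
    "unit", "level", "ref_year", "area_forest_ha", "area_faws_ha",
    "gai_forest_m3_ha_yr", "anl_forest_m3_ha_yr", "nai_forest_m3_ha_yr",
    "gai_faws_m3_ha_yr", "anl_faws_m3_ha_yr", "nai_faws_m3_ha_yr",
    "gai_forest_m3_yr", "anl_forest_m3_yr", "nai_forest_m3_yr",
    "gai_faws_m3_yr", "anl_faws_m3_yr", "nai_faws_m3_yr",
    "source", "uncertainty",
]
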