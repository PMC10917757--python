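"""Synthetic scenes with known truth for exercising the whole pipeline.

A scene is a set of co-registered 100 m grids — zone ids, tree cover, a
true forest mask, true and observed (biased, noisy, locally zeroed) biomass,
terrain, accessibility and protection covariates, red/NIR reflectance — plus
the tables a harmonisation run consumes: per-unit inventory-style truth
statistics, national SoEF-like time series, and modelled (CBM-like)
densities, all generated from one seed and mutually consistent by
construction. Because the truth is known exactly, every pipeline stage can
be tested for recovery rather than plausibility.

The temporal model is deliberately simple: national forest area and biomass
density follow linear trends anchored at the 2020 grids, and the observed
biomass map differs from the truth by a per-unit multiplicative bias, pixel
noise and one contiguous zero-biomass patch. What the generator does *not*
emulate — realistic geography, species composition, sensor artefacts — is
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import AdminUnit, CbmDensities, SoefSeries
from .faws import compute_kndvi
from .raster import Grid

__all__ = ["SceneConfig", "SyntheticScene", "make_scene", "make_nfi_tables"]

RULES_CONTINUOUS = ("slope", "altitude", "accessibility", "productivity")
RULES_BINARY = ("protected_area", "protected_species")


@dataclass
class SceneConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    grid_shape: Tuple[int, int] = (240, 240)
    pixel_area: float = 1.0                       # ha (100 m pixels)
    n_countries: int = 4
    subunits_per_country: int = 3
    seed: int = 0
    bias_range: Tuple[float, float] = (0.6, 1.5)  # per-unit map bias
    zero_patch_fraction: float = 0.03             # of the patch zone's forest
    noise_sd: float = 5.0                         # t/ha pixel noise
    smoothing_sigma: float = 6.0                  # px, random-field length
    forest_threshold_range: Tuple[float, float] = (15.0, 35.0)  # % cover
    agb_per_cover: float = 2.2                    # t/ha per % cover
    agb_noise_sd: float = 15.0                    # t/ha correlated field
    area_trend_range: Tuple[float, float] = (0.0005, 0.003)   # frac/yr
    density_trend_range: Tuple[float, float] = (0.002, 0.015)  # frac/yr
    d_young_frac: float = 0.25                    # young density / mean
    gsv_per_t: float = 2.0                        # m3 of GSV per t of AGB
    carbon_fraction: float = 0.5
    gai_range: Tuple[float, float] = (4.0, 8.0)   # m3/ha/yr
    anl_frac_range: Tuple[float, float] = (0.05, 0.15)
    faws_increment_uplift: float = 1.11           # FAWS vs forest per-ha
    restriction_frac_range: Tuple[float, float] = (0.01, 0.04)
    split_productivity_country: bool = True       # north/south split, 1st country
    mask_threshold_offset: float = -3.0           # observed mask bias, % cover
    species_prob_cut: float = 0.10
    nfi_year: int = 2012
    soef_years: Tuple[int, ...] = (1990, 1995, 2000, 2005, 2010, 2015, 2020)

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows < 8 or cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.n_countries < 1 or self.subunits_per_country < 1:
            raise ValueError("counts must be >= 1")
        if self.bias_range[0] <= 0:
            raise ValueError("bias range must be positive")
        if not 0 <= self.zero_patch_fraction < 1:
            raise ValueError("zero_patch_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.pixel_area <= 0:
            raise ValueError("noise_sd and pixel_area must be non-negative")
        if self.nfi_year >= 2020:
            raise ValueError("NFI year must precede the 2020 reference year")

    @property
    def n_zones(self) -> int:
        return self.n_countries * self.subunits_per_country


@dataclass
class SyntheticScene:
    """Co-registered grids plus the truth tables they aggregate to."""

    config: SceneConfig
    zone_map: Grid
    tree_cover: Grid
    forest_truth: Grid
    forest_observed: Grid
    agb_truth: Grid
    agb_observed: Grid
    elevation: Grid
    slope: Grid
    dist_road: Grid
    protected: Grid
    species_prob: Grid
    red: Grid
    nir: Grid
    kndvi: Grid
    exclusion: Grid
    zero_patch: Grid
    zero_patch_zone: int
    fnaws_truth: Grid
    faws_truth: Grid
    productivity_regions: Optional[Grid]
    units: List[AdminUnit]
    zone_of_unit: Dict[str, int]
    country_of_zone: Dict[int, str]
    bias_factors: Dict[int, float]
    truth_thresholds: Dict[str, Dict[str, Dict[int, float]]]
    restriction_stats: pd.DataFrame
    truth_stats: pd.DataFrame
    truth_increment: pd.DataFrame
    soef: Dict[str, SoefSeries]
    cbm: Dict[str, CbmDensities]
    country_trends: pd.DataFrame

    def country_zones(self, country: str) -> List[int]:
        return [z for z, c in self.country_of_zone.items() if c == country]

    def grids(self) -> Dict[str, Grid]:
        return {
            "zones": self.zone_map,
            "tree_cover": self.tree_cover,
            "forest_truth": self.forest_truth,
            "forest_observed": self.forest_observed,
            "agb_truth": self.agb_truth,
            "agb_observed": self.agb_observed,
            "elevation": self.elevation,
            "slope": self.slope,
            "dist_road": self.dist_road,
            "protected": self.protected,
            "species_prob": self.species_prob,
            "red": self.red,
            "nir": self.nir,
            "kndvi": self.kndvi,
            "exclusion": self.exclusion,
            "fnaws_truth": self.fnaws_truth,
            "faws_truth": self.faws_truth,
        }


def _country_code(i: int) -> str:
    return chr(65 + i // 26) + chr(65 + i % 26)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardised Gaussian-smoothed white noise (autocorrelated field)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _zone_layout(cfg: SceneConfig) -> Tuple[np.ndarray, Dict[int, str], Dict[str, int], List[AdminUnit]]:
    """Rectangular block partition: one horizontal band per country, split
    into vertical sub-unit blocks; exact zonal aggregates by construction."""
    rows, cols = cfg.grid_shape
    zones = np.zeros((rows, cols), dtype=np.int32)
    row_edges = np.linspace(0, rows, cfg.n_countries + 1).astype(int)
    col_edges = np.linspace(0, cols, cfg.subunits_per_country + 1).astype(int)
    country_of_zone: Dict[int, str] = {}
    zone_of_unit: Dict[str, int] = {}
    units: List[AdminUnit] = []
    zid = 0
    for ci in range(cfg.n_countries):
        cc = _country_code(ci)
        units.append(AdminUnit(code=cc, level=0))
        for si in range(cfg.subunits_per_country):
            zid += 1
            zones[row_edges[ci]:row_edges[ci + 1],
                  col_edges[si]:col_edges[si + 1]] = zid
            code = f"{cc}{si + 1}"
            units.append(AdminUnit(code=code, level=1, parent=cc))
            country_of_zone[zid] = cc
            zone_of_unit[code] = zid
    return zones, country_of_zone, zone_of_unit, units


def _carve_zero_patch(
    rng: np.random.Generator,
    observed: np.ndarray,
    forest: np.ndarray,
    zones: np.ndarray,
    zone: int,
    fraction: float,
) -> np.ndarray:
    """Zero a contiguous square patch of forest pixels inside one zone."""
    patch = np.zeros(observed.shape, dtype=bool)
    if fraction <= 0:
        return patch
    in_zone = zones == zone
    target = int(round(fraction * (forest & in_zone).sum()))
    if target == 0:
        return patch
    rr, cc = np.nonzero(in_zone)
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    rc, ccen = (r0 + r1) // 2, (c0 + c1) // 2
    half = 1
    while True:
        sq = np.zeros_like(patch)
        sq[max(r0, rc - half):min(r1 + 1, rc + half + 1),
           max(c0, ccen - half):min(c1 + 1, ccen + half + 1)] = True
        hit = sq & forest & in_zone
        if hit.sum() >= target or (sq & in_zone).sum() >= in_zone.sum():
            patch = hit
            break
        half += 1
    observed[patch] = 0.0
    return patch


def make_scene(config: Optional[SceneConfig] = None) -> SyntheticScene:
    """Generate a fully-specified scene; deterministic for a fixed seed."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.grid_shape
    pa = cfg.pixel_area
    sig = cfg.smoothing_sigma

    zones, country_of_zone, zone_of_unit, units = _zone_layout(cfg)
    countries = [_country_code(i) for i in range(cfg.n_countries)]
    country_band = np.empty(shape, dtype=object)
    for z, cc in country_of_zone.items():
        country_band[zones == z] = cc

    # --- continuous fields -------------------------------------------------
    tree_cover = np.clip(50.0 + 22.0 * _smooth_field(rng, shape, sig), 0.0, 100.0)
    thr = {cc: rng.uniform(*cfg.forest_threshold_range) for cc in countries}
    thr_map = np.vectorize(thr.get)(country_band).astype(float)
    forest = tree_cover > thr_map

    agb = np.clip(
        cfg.agb_per_cover * tree_cover
        + cfg.agb_noise_sd * _smooth_field(rng, shape, sig),
        0.0,
        None,
    )
    # any pixel above the forest cover threshold carries at least a young
    # stand's worth of biomass; zero forest biomass exists only where carved
    agb[forest] = np.maximum(agb[forest], 8.0)
    agb[~forest] = 0.0

    bias = {z: rng.uniform(*cfg.bias_range) for z in sorted(country_of_zone)}
    bias_map = np.ones(shape)
    for z, b in bias.items():
        bias_map[zones == z] = b
    observed = agb * bias_map
    if cfg.noise_sd > 0:
        observed = observed + rng.normal(0.0, cfg.noise_sd, shape)
    observed = np.clip(observed, 0.0, None)
    observed[forest] = np.maximum(observed[forest], 0.1)
    observed[~forest] = 0.0

    patch_zone = int(rng.integers(1, cfg.n_zones + 1))
    patch = _carve_zero_patch(
        rng, observed, forest, zones, patch_zone, cfg.zero_patch_fraction
    )

    elevation = np.clip(1200.0 + 700.0 * _smooth_field(rng, shape, sig), 0.0, None)
    res_m = 100.0 * np.sqrt(pa)  # pixel edge length in metres
    gy, gx = np.gradient(elevation, res_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    dist_road = np.clip(
        600.0
        + 450.0 * _smooth_field(rng, shape, sig)
        + 0.4 * (elevation - elevation.mean()),
        0.0,
        None,
    )
    protected = (_smooth_field(rng, shape, sig) > 1.8).astype(np.uint8)
    species_prob = np.clip(0.5 * (_smooth_field(rng, shape, sig) - 1.5), 0.0, 0.95)

    rel = agb / max(np.percentile(agb[forest], 95), 1e-9) if forest.any() else agb
    diff = np.clip(
        0.05 + 0.35 * rel + 0.04 * _smooth_field(rng, shape, sig), 0.0, 0.85
    )
    red = np.clip(0.10 + 0.02 * _smooth_field(rng, shape, sig), 0.02, 0.30)
    nir = np.clip(red + diff, 0.0, 0.99)

    def G(vals, nodata=np.nan) -> Grid:
        return Grid(vals, nodata=nodata, pixel_area=pa)

    kndvi = compute_kndvi(G(nir), G(red))

    # imperfect input mask (Copernicus-like) and non-candidate exclusion blob
    forest_obs = tree_cover > (thr_map + cfg.mask_threshold_offset)
    exclusion = (
        (~forest) & (tree_cover > 30.0)
        & (_smooth_field(rng, shape, sig) > 0.8)
    ).astype(np.uint8)

    # --- restriction truth -------------------------------------------------
    covar = {
        "slope": slope,
        "altitude": elevation,
        "accessibility": dist_road,
        "productivity": np.asarray(kndvi.values),
    }
    prod_regions = None
    if cfg.split_productivity_country:
        # first country split into a northern and a southern half for the
        # productivity rule (strong latitudinal gradient analogue)
        prod_regions = np.zeros(shape, dtype=np.int16)
        band0 = country_band == countries[0]
        rows0 = np.nonzero(band0.any(axis=1))[0]
        mid = (rows0.min() + rows0.max() + 1) // 2
        south = np.zeros(shape, bool)
        south[mid:, :] = True
        prod_regions[band0 & south] = 1

    truth_thresholds: Dict[str, Dict[str, Dict[int, float]]] = {}
    fnaws = np.zeros(shape, dtype=bool)
    restr_rows = []
    for cc in countries:
        in_c = country_band == cc
        cforest = forest & in_c
        truth_thresholds[cc] = {}
        for rule in RULES_CONTINUOUS:
            frac = rng.uniform(*cfg.restriction_frac_range)
            regions: Dict[int, np.ndarray] = {0: cforest}
            if rule == "productivity" and prod_regions is not None and cc == countries[0]:
                regions = {
                    0: cforest & (prod_regions == 0),
                    1: cforest & (prod_regions == 1),
                }
            truth_thresholds[cc][rule] = {}
            for region, rmask in regions.items():
                vals = covar[rule][rmask]
                if vals.size == 0:
                    continue
                if rule == "productivity":
                    t = float(np.quantile(vals, frac))
                    hit = rmask & (covar[rule] <= t)
                else:
                    t = float(np.quantile(vals, 1.0 - frac))
                    hit = rmask & (covar[rule] > t)
                truth_thresholds[cc][rule][region] = t
                fnaws |= hit
                restr_rows.append(
                    {"country": cc, "rule": rule, "region": region,
                     "area_ha": float(hit.sum() * pa)}
                )
        for rule, layer in (
            ("protected_area", protected.astype(bool)),
            ("protected_species", species_prob > cfg.species_prob_cut),
        ):
            hit = cforest & layer
            truth_thresholds[cc][rule] = {0: 1.0}
            fnaws |= hit
            restr_rows.append(
                {"country": cc, "rule": rule, "region": 0,
                 "area_ha": float(hit.sum() * pa)}
            )
    fnaws &= forest
    faws = forest & ~fnaws
    restriction_stats = pd.DataFrame(restr_rows)

    # --- per-unit truth statistics (reference year 2020) -------------------
    stats_rows = []
    for code, z in zone_of_unit.items():
        zf = forest & (zones == z)
        zfaws = faws & (zones == z)
        area = float(zf.sum() * pa)
        faws_area = float(zfaws.sum() * pa)
        stock = float(agb[zf].sum() * pa)
        baws = float(agb[zfaws].sum() * pa)
        stats_rows.append(
            {
                "unit": code, "zone": z, "level": 1, "ref_year": 2020,
                "country": country_of_zone[z],
                "forest_area_ha": area, "faws_area_ha": faws_area,
                "fnaws_area_ha": area - faws_area,
                "agb_t": stock,
                "agb_t_ha": stock / area if area > 0 else 0.0,
                "baws_t": baws, "bnaws_t": stock - baws,
                "source": "NFI", "uncertainty": 0,
            }
        )
    truth_stats = pd.DataFrame(stats_rows).set_index("unit")

    # --- temporal model, SoEF series and CBM densities ---------------------
    trend_rows = []
    soef: Dict[str, SoefSeries] = {}
    cbm: Dict[str, CbmDensities] = {}
    years = np.asarray(cfg.soef_years, dtype=float)
    incr_rows = []
    for cc in countries:
        sub = truth_stats[truth_stats["country"] == cc]
        a2020 = sub["forest_area_ha"].sum()
        s2020 = sub["agb_t"].sum()
        faws2020 = sub["faws_area_ha"].sum()
        baws2020 = sub["baws_t"].sum()
        d2020 = s2020 / a2020
        ra = rng.uniform(*cfg.area_trend_range)
        rd = rng.uniform(*cfg.density_trend_range)
        rg = rng.uniform(-0.004, 0.004)
        trend_rows.append(
            {"country": cc, "area_trend": ra, "density_trend": rd,
             "gai_trend": rg}
        )

        area_y = a2020 * (1.0 + ra * (years - 2020))
        dens_y = d2020 * (1.0 + rd * (years - 2020))
        agb_y = dens_y * area_y
        faws_share = faws2020 / a2020 if a2020 > 0 else 0.0
        baws_share = baws2020 / s2020 if s2020 > 0 else 0.0

        # per-unit increment truth for 2015, then national means for SoEF
        s_a15 = 1.0 + ra * (2015 - 2020)
        unit_incr = []
        for code, row in sub.iterrows():
            gai_f = rng.uniform(*cfg.gai_range)
            anl_f = gai_f * rng.uniform(*cfg.anl_frac_range)
            gai_w = gai_f * cfg.faws_increment_uplift
            anl_w = gai_w * rng.uniform(*cfg.anl_frac_range)
            af15 = row["forest_area_ha"] * s_a15
            aw15 = row["faws_area_ha"] * s_a15
            unit_incr.append((code, gai_f, anl_f, gai_w, anl_w, af15, aw15))
            incr_rows.append(
                {
                    "unit": code, "level": 1, "ref_year": 2015, "country": cc,
                    "area_forest_ha": af15, "area_faws_ha": aw15,
                    "gai_forest_m3_ha_yr": gai_f,
                    "anl_forest_m3_ha_yr": anl_f,
                    "nai_forest_m3_ha_yr": gai_f - anl_f,
                    "gai_faws_m3_ha_yr": gai_w,
                    "anl_faws_m3_ha_yr": anl_w,
                    "nai_faws_m3_ha_yr": gai_w - anl_w,
                    "source": "NFI", "uncertainty": 0,
                }
            )
        wf = np.array([u[5] for u in unit_incr])
        ww = np.array([u[6] for u in unit_incr])
        gai_f_nat = float(np.average([u[1] for u in unit_incr], weights=wf))
        anl_f_nat = float(np.average([u[2] for u in unit_incr], weights=wf))
        gai_w_nat = float(np.average([u[3] for u in unit_incr], weights=ww))
        anl_w_nat = float(np.average([u[4] for u in unit_incr], weights=ww))
        gai_shape = 1.0 + rg * (years - 2015)

        soef[cc] = SoefSeries(
            country=cc,
            years=years,
            forest_area=area_y,
            faws_area=faws_share * area_y,
            agb=agb_y,
            agb_carbon=cfg.carbon_fraction * agb_y,
            carbon_fraction=cfg.carbon_fraction,
            gsv=cfg.gsv_per_t * agb_y,
            gsv_faws=cfg.gsv_per_t * agb_y * baws_share,
            gai_forest_ha=gai_f_nat * gai_shape,
            nai_forest_ha=(gai_f_nat - anl_f_nat) * gai_shape,
            gai_faws_ha=gai_w_nat * gai_shape,
            nai_faws_ha=(gai_w_nat - anl_w_nat) * gai_shape,
        )

        d_nfi_nat = d2020 * (1.0 + rd * (cfg.nfi_year - 2020))
        for code, row in sub.iterrows():
            d_unit = row["agb_t_ha"]
            cbm[code] = CbmDensities(
                code=code,
                d_nfi_year=d_nfi_nat,
                d_2020=d2020,
                d_young=cfg.d_young_frac * d_unit if d_unit > 0 else 1e-6,
            )

    truth_increment = pd.DataFrame(incr_rows).set_index("unit")
    country_trends = pd.DataFrame(trend_rows).set_index("country")

    return SyntheticScene(
        config=cfg,
        zone_map=Grid(zones, nodata=0, pixel_area=pa),
        tree_cover=G(tree_cover),
        forest_truth=G(forest.astype(np.uint8), nodata=255),
        forest_observed=G(forest_obs.astype(np.uint8), nodata=255),
        agb_truth=G(agb),
        agb_observed=G(observed),
        elevation=G(elevation),
        slope=G(slope),
        dist_road=G(dist_road),
        protected=G(protected, nodata=255),
        species_prob=G(species_prob),
        red=G(red),
        nir=G(nir),
        kndvi=kndvi,
        exclusion=G(exclusion, nodata=255),
        zero_patch=G(patch.astype(np.uint8), nodata=255),
        zero_patch_zone=patch_zone,
        fnaws_truth=G(fnaws.astype(np.uint8), nodata=255),
        faws_truth=G(faws.astype(np.uint8), nodata=255),
        productivity_regions=(
            Grid(prod_regions, nodata=-1, pixel_area=pa)
            if prod_regions is not None else None
        ),
        units=units,
        zone_of_unit=zone_of_unit,
        country_of_zone=country_of_zone,
        bias_factors=bias,
        truth_thresholds=truth_thresholds,
        restriction_stats=restriction_stats,
        truth_stats=truth_stats,
        truth_increment=truth_increment,
        soef=soef,
        cbm=cbm,
        country_trends=country_trends,
    )


def truth_at_nfi_year(scene: SyntheticScene, nfi_year: int) -> pd.DataFrame:
    """Exact per-unit truth table at the NFI year, consistent with the
    forward temporal-updating model (CBM change factor on stable land plus
    the young-density afforestation term)."""
    cfg = scene.config
    rows = []
    for code, row in scene.truth_stats.iterrows():
        cc = row["country"]
        tr = scene.country_trends.loc[cc]
        s_a = 1.0 + tr["area_trend"] * (nfi_year - 2020)
        gf = 1.0 / (1.0 + tr["density_trend"] * (nfi_year - 2020))
        area_nfi = row["forest_area_ha"] * s_a
        delta_a = row["forest_area_ha"] - area_nfi
        d_young = scene.cbm[code].d_young
        stock_nfi = (row["agb_t"] - delta_a * d_young) / gf
        faws_nfi = row["faws_area_ha"] * s_a
        baws_nfi = (
            row["baws_t"] * stock_nfi / row["agb_t"] if row["agb_t"] > 0 else 0.0
        )
        rows.append(
            {
                "unit": code, "zone": row["zone"], "level": 1,
                "ref_year": nfi_year, "country": cc,
                "forest_area_ha": area_nfi, "faws_area_ha": faws_nfi,
                "fnaws_area_ha": area_nfi - faws_nfi,
                "agb_t": stock_nfi,
                "agb_t_ha": stock_nfi / area_nfi if area_nfi > 0 else 0.0,
                "baws_t": baws_nfi, "bnaws_t": stock_nfi - baws_nfi,
                "source": "NFI", "uncertainty": 0,
            }
        )
    return pd.DataFrame(rows).set_index("unit")


def make_nfi_tables(
    scene: SyntheticScene,
    nfi_year: Optional[int] = None,
    sampling_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Inventory-style tables: truth at the NFI year with relative sampling
    noise ``sampling_sd`` (0 returns the truth exactly).

    Returns (forest statistics, increment statistics) per unit. FAWS never
    exceeds the total, BAWS never exceeds the stock, and GAI = NAI + ANL
    holds exactly in every generated row.
    """
    if sampling_sd < 0:
        raise ValueError("sampling_sd must be non-negative")
    cfg = scene.config
    nfi_year = cfg.nfi_year if nfi_year is None else nfi_year
    if nfi_year >= 2020:
        raise ValueError("NFI year must precede the 2020 reference year")
    rng = rng or np.random.default_rng(cfg.seed + 1)

    stats = truth_at_nfi_year(scene, nfi_year).copy()
    if sampling_sd > 0:
        n = len(stats)
        for col in ("forest_area_ha", "agb_t", "faws_area_ha", "baws_t"):
            stats[col] = stats[col] * (1.0 + rng.normal(0, sampling_sd, n))
        stats["faws_area_ha"] = stats[["faws_area_ha", "forest_area_ha"]].min(axis=1)
        stats["baws_t"] = stats[["baws_t", "agb_t"]].min(axis=1)
    stats["fnaws_area_ha"] = stats["forest_area_ha"] - stats["faws_area_ha"]
    stats["bnaws_t"] = stats["agb_t"] - stats["baws_t"]
    stats["agb_t_ha"] = np.where(
        stats["forest_area_ha"] > 0,
        stats["agb_t"] / stats["forest_area_ha"],
        0.0,
    )

    incr = scene.truth_increment.copy()
    if sampling_sd > 0:
        n = len(incr)
        for cat in ("forest", "faws"):
            gai = incr[f"gai_{cat}_m3_ha_yr"] * (
                1.0 + rng.normal(0, sampling_sd, n)
            )
            anl = incr[f"anl_{cat}_m3_ha_yr"] * (
                1.0 + rng.normal(0, sampling_sd, n)
            )
            anl = np.minimum(anl, 0.95 * gai)
            incr[f"gai_{cat}_m3_ha_yr"] = gai
            incr[f"anl_{cat}_m3_ha_yr"] = anl
            incr[f"nai_{cat}_m3_ha_yr"] = gai - anl
    return stats, incr
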