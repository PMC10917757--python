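"""End-to-end orchestration: statistics harmonisation through map outputs.

Stage order is fixed: harmonise the tabular statistics to the reference
year; adjust the forest mask to the harmonised areas; infill zero-biomass
forest; bias-adjust the biomass map; calibrate restriction thresholds and
derive the FAWS masks and biomass map; harmonise increments; run the
map-vs-statistics coherence check. Outputs are four rasters (forest mask,
FAWS mask, adjusted biomass, FAWS biomass), two statistics tables and a
comparison report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import biomass_map, faws as faws_mod, increment as incr_mod, stats as stats_mod
from .core import CbmDensities, SoefSeries, assign_uncertainty
from .raster import Grid, adjust_mask_to_area, write_grid, zonal_stats
from .synthetic import SceneConfig, SyntheticScene, make_nfi_tables, make_scene
from .validation import ComparisonReport, coherence_check

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "harmonise_forest_stats",
    "harmonise_increment_stats",
    "build_restriction_rules",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-scene pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    nfi_year: Optional[int] = None          # default: scene config's NFI year
    sampling_sd: float = 0.0
    target_year: int = 2020
    increment_ref_year: int = 2015
    area_tolerance: float = stats_mod.DEFAULT_AREA_TOLERANCE
    factor_clamp: Optional[Tuple[float, float]] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.increment_ref_year > self.target_year:
            raise ValueError("increment reference year after target year")


def harmonise_forest_stats(
    nfi: pd.DataFrame,
    soef: Mapping[str, SoefSeries],
    cbm: Mapping[str, CbmDensities],
    target_year: int = 2020,
    area_tolerance: float = stats_mod.DEFAULT_AREA_TOLERANCE,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonise per-unit NFI statistics to the target year.

    ``nfi`` has one row per unit with columns ``country``, ``ref_year``,
    ``forest_area_ha``, ``agb_t``, ``faws_area_ha``, ``baws_t``. Per
    country: the national forest area is reconciled against the SoEF series
    (2% rule), sub-national areas are rescaled to the national figure, each
    unit's biomass is updated with the modelled density change plus the net
    afforestation/deforestation terms, and FAWS area / biomass follow the
    totals proportionally. Returns the harmonised table and a per-country
    decision log.
    """
    out_rows = []
    decisions = []
    for cc, sub in nfi.groupby("country"):
        series = soef[cc]
        nfi_year = int(sub["ref_year"].iloc[0])
        nat_area_nfi = float(sub["forest_area_ha"].sum())
        nat_target, decision = stats_mod.reconcile_forest_area(
            nat_area_nfi, nfi_year, series, target_year,
            area_tolerance=area_tolerance,
        )
        decisions.append(
            {
                "country": cc,
                "mode": decision.mode.value,
                "rel_diff": decision.rel_diff,
                "annual_change_ha_yr": decision.annual_change,
                "years_elapsed": decision.years_elapsed,
                "national_area_target_ha": nat_target,
            }
        )
        areas_2020 = stats_mod.rescale_subnational(
            sub["forest_area_ha"].to_numpy(), nat_target
        )
        for (code, row), area_2020 in zip(sub.iterrows(), areas_2020):
            area_nfi = row["forest_area_ha"]
            stock_nfi = row["agb_t"]
            unit_cbm = cbm.get(code) or cbm.get(cc)
            if unit_cbm is not None:
                factor = unit_cbm.change_factor
                d_young = unit_cbm.d_young
            else:
                factor = stats_mod.soef_change_factor(
                    series, nfi_year, target_year
                )
                d_young = 0.25 * (stock_nfi / area_nfi if area_nfi > 0 else 0.0)
            d_mean = stock_nfi / area_nfi if area_nfi > 0 else 0.0
            aff, deff = stats_mod.split_net_area_change(area_2020 - area_nfi)
            stock_2020 = stock_nfi * factor + stats_mod.area_change_biomass(
                aff, deff, d_young, d_mean
            )
            faws_2020 = stats_mod.temporal_update_faws(
                row["faws_area_ha"], area_nfi, area_2020
            )
            faws_2020 = min(faws_2020, area_2020)
            baws_2020 = (
                stats_mod.temporal_update_faws(row["baws_t"], stock_nfi, stock_2020)
                if stock_nfi > 0 else 0.0
            )
            baws_2020 = min(baws_2020, stock_2020)
            out_rows.append(
                {
                    "unit": code,
                    "zone": row.get("zone", np.nan),
                    "level": row.get("level", 1),
                    "ref_year": target_year,
                    "country": cc,
                    "forest_area_ha": area_2020,
                    "faws_area_ha": faws_2020,
                    "fnaws_area_ha": area_2020 - faws_2020,
                    "agb_t": stock_2020,
                    "agb_t_ha": stock_2020 / area_2020 if area_2020 > 0 else 0.0,
                    "baws_t": baws_2020,
                    "bnaws_t": stock_2020 - baws_2020,
                    "source": row.get("source", "NFI"),
                    "uncertainty": assign_uncertainty(row.get("source", "NFI")),
                }
            )
    return (
        pd.DataFrame(out_rows).set_index("unit"),
        pd.DataFrame(decisions).set_index("country"),
    )


def harmonise_increment_stats(
    incr: pd.DataFrame,
    soef: Mapping[str, SoefSeries],
    nfi_periods: Mapping[str, Tuple[int, int]],
    ref_year: int = 2015,
) -> pd.DataFrame:
    """Adjust per-unit increment statistics to the reference year and match
    the category areas to the SoEF figures for that year.

    Per-ha values get the national SoEF-based correction factor (identity
    for inventory periods already inside 2010-2020); unit areas are rescaled
    so national sums match the SoEF areas at the reference year; totals are
    recomputed as per-ha times area.
    """
    out = []
    for cc, sub in incr.groupby("country"):
        series = soef[cc]
        period = nfi_periods.get(cc, (2010, 2020))
        area_f = sub["area_forest_ha"].to_numpy(float)
        area_w = sub["area_faws_ha"].to_numpy(float)
        sf = series.value_at("forest_area", ref_year) / area_f.sum()
        sw = series.value_at("faws_area", ref_year) / area_w.sum()
        for i, (code, row) in enumerate(sub.iterrows()):
            rec = {
                "unit": code, "level": row.get("level", 1),
                "ref_year": ref_year, "country": cc,
                "area_forest_ha": area_f[i] * sf,
                "area_faws_ha": area_w[i] * sw,
                "source": row.get("source", "NFI"),
                "uncertainty": int(row.get("uncertainty", 0)),
            }
            for cat in ("forest", "faws"):
                gai = row[f"gai_{cat}_m3_ha_yr"]
                anl = row[f"anl_{cat}_m3_ha_yr"]
                gai2, anl2, nai2, adj = incr_mod.temporal_adjust_increment(
                    gai, anl, period, series, ref_year=ref_year
                )
                rec[f"gai_{cat}_m3_ha_yr"] = gai2
                rec[f"anl_{cat}_m3_ha_yr"] = anl2
                rec[f"nai_{cat}_m3_ha_yr"] = nai2
                area_cat = rec[f"area_{cat}_ha"]
                rec[f"gai_{cat}_m3_yr"] = incr_mod.totals_from_perha(gai2, area_cat)
                rec[f"anl_{cat}_m3_yr"] = incr_mod.totals_from_perha(anl2, area_cat)
                rec[f"nai_{cat}_m3_yr"] = incr_mod.totals_from_perha(nai2, area_cat)
            out.append(rec)
    return pd.DataFrame(out).set_index("unit")


def build_restriction_rules(
    scene: SyntheticScene,
    restriction_targets: pd.DataFrame,
) -> List[faws_mod.RestrictionRule]:
    """Calibrated restriction rules for a scene.

    ``restriction_targets`` has columns country, rule, region, area_ha (the
    per-restriction reference statistics). Thresholds are calibrated at
    country scale — each country is one calibration region — except where a
    country has a north/south productivity split, which contributes two
    independent regions.
    """
    cfg = scene.config
    countries = sorted({c for c in scene.country_of_zone.values()})
    cidx = {cc: i for i, cc in enumerate(countries)}
    zones = np.asarray(scene.zone_map.values)
    country_region = np.zeros(zones.shape, dtype=np.int16)
    for z, cc in scene.country_of_zone.items():
        country_region[zones == z] = cidx[cc]

    layer = {
        "slope": scene.slope,
        "altitude": scene.elevation,
        "accessibility": scene.dist_road,
        "productivity": scene.kndvi,
        "protected_area": scene.protected,
        "protected_species": Grid(
            (np.asarray(scene.species_prob.values) > cfg.species_prob_cut
             ).astype(np.uint8),
            nodata=255, pixel_area=scene.zone_map.pixel_area,
        ),
    }

    rules = []
    for rule_name, grid in layer.items():
        regions = country_region.copy()
        if (
            rule_name == "productivity"
            and scene.productivity_regions is not None
        ):
            south = np.asarray(scene.productivity_regions.values) == 1
            regions = regions + len(countries) * south.astype(np.int16)
        rule = faws_mod.RestrictionRule(
            name=rule_name,
            grid=grid,
            calibration_regions=Grid(
                regions, nodata=-1, pixel_area=scene.zone_map.pixel_area
            ),
        )
        targets: Dict[int, float] = {}
        sub = restriction_targets[restriction_targets["rule"] == rule_name]
        for _, row in sub.iterrows():
            rid = cidx[row["country"]] + len(countries) * int(row["region"])
            targets[rid] = float(row["area_ha"])
        faws_mod.calibrate_threshold(rule, scene.forest_truth, targets)
        rules.append(rule)
    return rules


_SOEF_FIELDS = {
    "forest_area": "forest_area_ha",
    "faws_area": "faws_area_ha",
    "agb": "agb_t",
    "agb_carbon": "agb_carbon_tc",
    "gsv": "gsv_m3",
    "gsv_faws": "gsv_faws_m3",
    "gai_forest_ha": "gai_forest_m3_ha_yr",
    "nai_forest_ha": "nai_forest_m3_ha_yr",
    "gai_faws_ha": "gai_faws_m3_ha_yr",
    "nai_faws_ha": "nai_faws_m3_ha_yr",
}


def load_soef_csv(path) -> Dict[str, SoefSeries]:
    """Read SoEF-like national series from a long CSV (one row per country
    and year; missing columns are simply not reported)."""
    df = pd.read_csv(path)
    out: Dict[str, SoefSeries] = {}
    for cc, sub in df.groupby("country"):
        sub = sub.sort_values("year")
        kwargs = {}
        for attr, col in _SOEF_FIELDS.items():
            if col in sub.columns and sub[col].notna().any():
                kwargs[attr] = sub[col].to_numpy(float)
        if "carbon_fraction" in sub.columns:
            kwargs["carbon_fraction"] = float(sub["carbon_fraction"].iloc[0])
        out[cc] = SoefSeries(country=cc, years=sub["year"].to_numpy(float), **kwargs)
    return out


def load_cbm_csv(path) -> Dict[str, CbmDensities]:
    """Read modelled densities from a CSV with columns code, d_nfi_year,
    d_2020, d_young."""
    df = pd.read_csv(path)
    return {
        str(row["code"]): CbmDensities(
            code=str(row["code"]),
            d_nfi_year=float(row["d_nfi_year"]),
            d_2020=float(row["d_2020"]),
            d_young=float(row["d_young"]),
        )
        for _, row in df.iterrows()
    }


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    scene: SyntheticScene
    nfi_stats: pd.DataFrame
    nfi_increment: pd.DataFrame
    stats_2020: pd.DataFrame
    area_decisions: pd.DataFrame
    increment_2015: pd.DataFrame
    forest_mask: Grid
    mask_report: pd.DataFrame
    agb_adjusted: Grid
    bias_factors: pd.DataFrame
    fnaws_mask: Grid
    faws_mask: Grid
    baws_map: Grid
    rules: List[faws_mod.RestrictionRule]
    report: ComparisonReport


def run_pipeline(config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full pipeline on a synthetic scene.

    Identical configs (and seeds) produce identical outputs. When
    ``config.out_dir`` is set, rasters, tables and the report are written
    there.
    """
    cfg = config or PipelineConfig()
    scene = make_scene(cfg.scene)
    nfi_year = cfg.nfi_year or cfg.scene.nfi_year
    nfi_stats, nfi_incr = make_nfi_tables(
        scene, nfi_year=nfi_year, sampling_sd=cfg.sampling_sd
    )

    # 1. tabular harmonisation to the target year
    stats_2020, decisions = harmonise_forest_stats(
        nfi_stats, scene.soef, scene.cbm,
        target_year=cfg.target_year, area_tolerance=cfg.area_tolerance,
    )

    # 2. forest mask matched to the harmonised areas
    targets = {
        int(row["zone"]): row["forest_area_ha"]
        for _, row in stats_2020.reset_index().iterrows()
    }
    forest_mask, mask_report = adjust_mask_to_area(
        scene.forest_observed, scene.tree_cover, scene.exclusion,
        targets, scene.zone_map,
    )

    # 3. zero-biomass infill, calibrated on the zone carrying the zero patch
    agb = scene.agb_observed
    if cfg.scene.zero_patch_fraction > 0:
        region = [scene.zero_patch_zone]
        model = biomass_map.fit_cover_model(
            agb, scene.tree_cover, forest_mask, scene.zone_map, region
        )
        agb = biomass_map.infill_zero_biomass(
            agb, model, forest_mask, scene.tree_cover, scene.zone_map, region
        )

    # 4. per-unit bias adjustment to the harmonised densities
    ref_density = {
        int(row["zone"]): row["agb_t_ha"]
        for _, row in stats_2020.reset_index().iterrows()
    }
    agb_adjusted, factors = biomass_map.bias_adjust_map(
        agb, scene.zone_map, forest_mask, ref_density,
        factor_clamp=cfg.factor_clamp,
    )

    # 5. FAWS: calibrate restrictions, build masks, mask the biomass
    rules = build_restriction_rules(scene, scene.restriction_stats)
    fnaws_mask, faws_mask = faws_mod.build_fnaws_mask(rules, forest_mask)
    baws_map = faws_mod.faws_biomass_map(agb_adjusted, faws_mask)

    # 6. increment harmonisation
    periods = {cc: (2010, 2020) for cc in scene.soef}
    increment_2015 = harmonise_increment_stats(
        nfi_incr, scene.soef, periods, ref_year=cfg.increment_ref_year
    )

    # 7. coherence of maps against the statistics that calibrated them
    s = stats_2020.reset_index()
    report = coherence_check(
        scene.zone_map,
        forest_mask,
        agb_adjusted,
        ref_area={int(r["zone"]): r["forest_area_ha"] for _, r in s.iterrows()},
        ref_stock={int(r["zone"]): r["agb_t"] for _, r in s.iterrows()},
        faws_mask=faws_mask,
        fnaws_mask=fnaws_mask,
        ref_faws_area={int(r["zone"]): r["faws_area_ha"] for _, r in s.iterrows()},
        ref_baws_stock={int(r["zone"]): r["baws_t"] for _, r in s.iterrows()},
    )

    result = PipelineResult(
        scene=scene,
        nfi_stats=nfi_stats,
        nfi_increment=nfi_incr,
        stats_2020=stats_2020,
        area_decisions=decisions,
        increment_2015=increment_2015,
        forest_mask=forest_mask,
        mask_report=mask_report,
        agb_adjusted=agb_adjusted,
        bias_factors=factors,
        fnaws_mask=fnaws_mask,
        faws_mask=faws_mask,
        baws_map=baws_map,
        rules=rules,
        report=report,
    )
    if cfg.out_dir:
        write_outputs(result, cfg.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the map and table outputs of a run to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grid(out / "forest_map_2020.tif", result.forest_mask)
    write_grid(out / "faws_map_2020.tif", result.faws_mask)
    write_grid(out / "biomass_map_2020.tif", result.agb_adjusted)
    write_grid(out / "baws_map_2020.tif", result.baws_map)
    result.stats_2020.to_csv(out / "biomass_statistics_2020.csv")
    result.increment_2015.to_csv(out / "increment_statistics_2015.csv")
    result.bias_factors.to_csv(out / "bias_factors.csv")
    result.mask_report.to_csv(out / "mask_adjustment.csv")
    result.area_decisions.to_csv(out / "area_decisions.csv")
    result.report.table.to_csv(out / "coherence_report.csv", index=False)
    rows = []
    for rule in result.rules:
        for region, t in rule.thresholds.items():
            rows.append(
                {"rule": rule.name, "region": region, "threshold": t,
                 "provenance": rule.provenance, "uncertainty": rule.uncertainty}
            )
    pd.DataFrame(rows).to_csv(out / "faws_thresholds.csv", index=False)
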