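# forestharm

Harmonised forest statistics and maps: temporal updating of inventory
biomass and wood-supply statistics, area-matched forest masking, per-unit
bias adjustment of biomass rasters, threshold-calibrated mapping of
wood-supply restrictions, and increment gap-filling with provenance and
uncertainty labels.

## The problem

National Forest Inventories (NFIs) report forest area, aboveground biomass
(AGB), the share available for wood supply (FAWS), and volume increment —
but each country uses its own definitions, reference years and spatial
scales, and satellite biomass maps disagree systematically with inventory
statistics. Producing a coherent continental picture requires:

* **reconciling forest areas** between the NFI and the national reporting
  series (SoEF): a relative difference below 2% is treated as negligible
  and the reporting series is adopted; a larger gap indicates a genuinely
  different forest definition and the NFI area is extended by the series'
  annual change, `A(t) = A_NFI + ΔA·(t − t_NFI)`;
* **temporal updating of biomass** to a common reference year with a
  modelled density change factor, `d₂₀₂₀ = d_NFI · (1 + (D₂₀₂₀ −
  D_NFI)/D_NFI)`, plus stock terms for net afforestation (valued at the
  young-stand density) and deforestation (at the unit's mean density);
* **zonal bias adjustment** of a biomass raster: each reporting unit *z*
  is multiplied by `f_z = d_ref,z / mean(map | forest pixels of z)`, so the
  adjusted map reproduces the reference statistics exactly at the unit
  scale — after first matching the forest mask to the area statistics
  (converting lowest-tree-cover forest pixels out, or highest-cover
  non-forest candidates in) and infilling zero-biomass forest from a local
  tree-cover regression;
* **restriction mapping**: six layers (slope, altitude, protected areas,
  protected species, accessibility, productivity via kNDVI =
  tanh(((NIR−RED)/2σ)²), σ = 0.15) with per-country thresholds *calibrated*
  so each restricted forest area matches its reference statistic; FNAWS is
  their union and FAWS its complement;
* **increment harmonisation**: GAI = NAI + ANL throughout; per-ha values
  are moved to the 2015 reference year with the SoEF-based factor
  `c = GAI_SoEF(2015) / mean(GAI_SoEF over NFI period)`, natural losses
  kept as a stable share of the gross increment, and missing categories
  gap-filled by a decision tree (copy when areas are <15% apart, SoEF
  cross-category ratio, neighbour-country ratio) with uncertainty labels
  0–3 recording provenance.

Everything is exercised on synthetic scenes with known truth: block-zoned
landscapes with smooth tree-cover and biomass fields, per-unit
multiplicative map bias, a carved zero-biomass patch, terrain-correlated
restriction covariates and consistent SoEF-like time series — so each
stage is tested for *recovery*, not plausibility.

## Worked example

```python
from forestharm.pipeline import PipelineConfig, run_pipeline
from forestharm.synthetic import SceneConfig

res = run_pipeline(PipelineConfig(scene=SceneConfig(seed=42)))
print(res.stats_2020[["forest_area_ha", "agb_t_ha", "faws_area_ha"]].head(4))
print(res.bias_factors["factor"].head(4))
for k, v in res.report.rmae_by_quantity.items():
    print(f"{k:16s} rMAE = {v:.2e}")
```

prints (240×240 scene, 4 countries × 3 units):

```
      forest_area_ha  agb_t_ha  faws_area_ha
unit
AA1           3984.0    126.69        3495.0
AA2           4283.0    133.76        4013.0
AA3           3158.0    106.56        2727.0
AB1           4694.0    145.37        4124.0

zone
1    0.7266
2    0.9543
3    0.7763
4    1.1417
Name: factor, dtype: float64

agb_stock_t      rMAE = 1.91e-15
baws_stock_t     rMAE = 2.91e-04
faws_area_ha     rMAE = 1.03e-16
fnaws_area_ha    rMAE = 3.30e-16
forest_area_ha   rMAE = 1.37e-16
```

The harmonised 2020 table carries each unit's reconciled area, updated
density and FAWS share; the per-zone factors are the multiplicative
corrections applied to the observed biomass map (zone 1 was biased high by
×1.38, hence factor ≈ 0.73); and the residual divergence between the
output maps and the statistics that calibrated them is at floating-point /
one-pixel level — the map and table deliverables are mutually coherent.
In this run the FAWS share is 85.1% of forest area by both the statistics
and the map.

The same stages are available from the shell:

```sh
forestharm simulate --seed 42 --out scene/
forestharm run-all  --seed 42 --out run/
```

## Layout

| module | contents |
|---|---|
| `forestharm.core` | domain types, units, uncertainty labels 0–3, carbon↔biomass |
| `forestharm.synthetic` | scene generator and inventory-table sampler |
| `forestharm.raster` | `Grid`, zonal statistics, area-matched mask adjustment, TIFF I/O |
| `forestharm.stats` | area reconciliation (2% rule), temporal updating, FAWS/BAWS derivation |
| `forestharm.biomass_map` | cover–biomass model, zero-biomass infill, zonal bias adjustment |
| `forestharm.faws` | kNDVI, restriction rules, threshold calibration, FNAWS/FAWS masks |
| `forestharm.increment` | increment temporal adjustment and gap-filling decision tree |
| `forestharm.validation` | rMAE and map-vs-statistics coherence reports |
| `forestharm.pipeline` | end-to-end orchestration; `forestharm.cli` the console entry point |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
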