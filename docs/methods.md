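# Methods

This note documents the models and procedures implemented in `forestharm`,
the defaults and why they were chosen, what the synthetic scenes do and do
not emulate, and the numerical conventions that matter for reproducing the
outputs.

## Scope and units

The package harmonises area-level forest statistics (not plot data) and
adjusts co-registered rasters against them. Units are fixed package-wide:
hectares for area, tonnes of dry aboveground biomass (AGB), tonnes of
carbon, cubic metres for growing stock volume (GSV), m³/ha/yr and m³/yr for
increment. Densities are stored alongside totals and reconciled on
construction so `density × area = stock` always holds. Missing values are
NaN — an explicit sentinel distinct from zero, because gap-filling logic
branches on missingness and zero biomass is a legal value. Plot-level
estimation, biomass expansion factors and the internals of the forest
carbon model whose density outputs we consume are upstream of this package.

## Statistics harmonisation

**Area reconciliation (2% rule).** The NFI forest area is compared with the
reporting-series (SoEF) value interpolated at the NFI year (or, with
interpolation off, at the closest reported year, ties to the earlier one).
The relative difference is expressed against the NFI area, matching the
convention in which a reporting series is described as "N% lower" than the
inventory. At or below the tolerance (default 0.02, configurable
`area_tolerance`) the difference is attributed to plot data being acquired
over several years, and the SoEF area at the target year is adopted;
above it the two sources define forest differently, and the NFI area is
extended by the SoEF least-squares annual trend times the elapsed years. A
second, purely descriptive band (`area_flag`, default 0.05) marks
substantial divergences in the logs. Sub-national areas are then rescaled
linearly so their sum equals the national figure.

**Temporal updating of biomass.** Stocks move from the NFI year to 2020 by
the modelled relative density change on stable forest land (the
carbon-budget-model densities at the two years), plus a signed stock term
for net area change: afforested area valued at the modelled young-stand
(age 0–19) density, deforested area at the unit's mean density. When only
a net area change is known, a positive net is treated as afforestation and
a negative one as deforestation. Countries without modelled densities fall
back to the relative change of the SoEF biomass series. The change factor
is applied at the finest granularity available (`cbm_scope` behaviour:
per-unit densities when present, national otherwise).

**FAWS.** FAWS area and biomass are updated proportionally to the change
in the corresponding total (a 2% total increase raises FAWS by 2%), which
preserves FNAWS = forest − FAWS ≥ 0. Where availability is only reported
as growing stock, BAWS = AGB × GSV_faws / GSV_total.

**Uncertainty labels.** 0 = harmonised NFI; 1 = SoEF- or CBM-derived
(CBM's label is configurable, default 1, since it is a modelled national
source of the same standing as the reporting database); 2 = gap-filled
from the same country; 3 = gap-filled from other countries. Labelling is
idempotent given the same provenance.

## Mask adjustment

Per zone, the mapped forest area is forced to the statistic by converting
forest pixels with the lowest tree cover to non-forest (excess) or
non-forest, non-excluded pixels with the highest tree cover to forest
(deficit). The exclusion layer stands for tree cover in urban or
agricultural context. Ties in cover are broken by row-major pixel index,
making the output reproducible bit-for-bit; the achieved area is within
one pixel (1 ha) of the target, which is the quantisation floor of any
area-matched 100 m product, and the operation is idempotent. Edge-priority
growth is approximated by cover ranking alone; an adjacency preference was
considered and left out because cover ranking already recovers the area
target exactly and the true expansion ordering is not specified by any
input we consume. Targets exceeding the attainable area are flagged and
the best achievable mask returned.

## Biomass map correction

Order is fixed: mask → infill → bias-adjust. Masking first makes map and
statistics refer to the same area; infilling before adjustment prevents
zero-biomass zones from inflating the correction factors.

**Zero-biomass infill.** An ordinary least-squares regression of biomass
on tree cover is fitted over the calibration region on forest pixels with
positive biomass (≥100 by default), and applied only to zero-valued (and,
by default, nodata) forest pixels of the same region, floored at zero and
capped at the region's observed maximum. The relation saturates with
canopy closure, so the model is deliberately local — in the pipeline the
calibration region is the single zone containing the zero patch.

**Bias adjustment.** The correction factor per zone is the ratio of the
reference density to the map's forest-pixel mean; applied multiplicatively
it reproduces the reference mean to 1e-9 relative and conserves the zonal
stock at `ref_density × area`. A regression-based bias model across units
was rejected: with few sub-national units per country its parameters would
be poorly determined and the adjusted map would no longer match the
statistics. Factors are unbounded by default; an optional clamp guards
degenerate synthetic zones at the cost of exactness in clamped zones.

## Restriction mapping and FAWS

Six restriction layers are supported: slope, altitude and
distance-to-road restrict *above* a threshold, productivity (kNDVI, sigma
0.15) restricts *below*, protected areas and protected species are binary
class layers (species candidacy = occurrence probability > 0.10 on the
matching forest type). Thresholds are calibrated per country — per region
where a country is split, e.g. north/south for productivity along a strong
ecological gradient — by exact search over the sorted unique forest-pixel
values, equivalent to reading a quantile; the restricted area is within
one pixel of the best attainable and ties restrict the smaller area. The
quantile convention is strict (>) for restricted-above and inclusive (≤)
for restricted-below. Countries without restriction statistics inherit
thresholds from configured neighbour countries (copy for one donor,
arithmetic mean for several) at uncertainty 3. Typical calibrated values
(~30° slope, 2000 m altitude, ~1000 m to roads, kNDVI 0.1–0.2) are
shipped as priors only.

FNAWS is the union of the calibrated restricted sets, FAWS its complement
within the forest mask — the two partition the forest exactly. Because
restrictions are calibrated independently, the unioned FNAWS area can
differ from the sum of per-restriction statistics where restrictions
overlap; the validation report shows both. An optional per-rule exclusion
list removes pixels already claimed by earlier rules from a rule's
calibration pool, for restrictions nested inside others.

## Increment

GAI = NAI + ANL is enforced (1e-9 absolute on per-ha values) after every
operation. Inventory periods inside 2010–2020 are taken as representative
of the 2015 reference year and left unadjusted; otherwise the per-ha GAI
is scaled by the national SoEF FAWS-GAI ratio `GAI(2015)/mean(GAI over the
period)` — the FAWS series is used because it is the more densely sampled
and more reliably reported category, and the same factor is applied to
both categories (flagged in the logs when a country reports
forest-category values). The mean over the period is a trapezoidal average
of the linearly interpolated series; with 5-yearly reporting any heavier
averaging rule would be false precision. ANL is treated as a stable share
of GAI, so the corrected ANL keeps the pre-correction ratio and NAI
follows by difference. Totals are always per-ha × category area, with
areas matched to the reporting series at the reference year.

Gap-filling of a missing category: (1) areas within 15% → per-ha values
copied, uncertainty 2; (2) SoEF reports both categories → national
cross-category per-ha ratio, uncertainty 2; (3) configured neighbour's
ratio, uncertainty 3. A missing component (e.g. NAI from GAI) can be
filled with a borrowed NAI/GAI ratio. Category attribution (whether a
country's values describe forest or FAWS) is an input column, resolved
upstream by area comparison, not inferred here.

## Synthetic scenes

The generator emulates the input stack: a rectangular block partition into
countries and sub-units (exact zonal aggregates by construction), smooth
tree-cover and biomass random fields (Gaussian-filtered white noise,
length 6 px — no specific spatial model is claimed, only autocorrelation),
forest = cover above a per-country threshold (15–35%), biomass ≈ 2.2 t/ha
per % cover with a correlated 15 t/ha field and an 8 t/ha forest floor.
The observed map differs from truth by a per-unit multiplicative bias
drawn in [0.6, 1.5], optional pixel noise (default sd 5 t/ha), and one
contiguous zero patch (3% of one zone's forest) to exercise infill.
Terrain, accessibility (correlated with elevation), protection blobs,
species probability and reflectances (NIR−RED increasing with biomass, so
kNDVI tracks productivity, Spearman ρ > 0.5) drive the restriction truth,
with per-country restricted fractions of 1–4% per rule so the FNAWS share
lands near the European ~15%. National series follow linear trends
anchored at the 2020 grids: area +0.05–0.3 %/yr, density +0.2–1.5 %/yr
(inside the reported 0.1–1.8 %/yr national range), FAWS per-ha increment
11% above forest (the average cross-category gap in the reporting data).
The truth at the NFI year is defined by inverting the forward updating
model, so with zero sampling noise the pipeline must recover the 2020
truth exactly — that is the point of the construction, and the end-to-end
tests assert it at 1e-6 relative.

What the scenes do **not** emulate: real geography and NUTS geometry,
species composition, sensor artefacts and cloud gaps, non-linear national
trends, reporting-series revisions, or sampling-design effects beyond
i.i.d. relative noise. Passing tests therefore demonstrate the
correctness of the harmonisation machinery, not the accuracy of any
real-world product derived with it.

## Numerical conventions and problem sizes

Default scenes are 240×240 pixels (1 ha each) with 12 zones; unit tests
use 64×64 where a per-pixel loop oracle is compared. Determinism: every
random draw comes from one seeded generator; no global state. Grids are
float64 in memory, written as float32 (masks as 8-bit) single-band TIFFs
with nodata, pixel area and transform in a JSON tag. Zonal means of empty
zones are NaN and flagged, never silently zero. Threshold sentinels: +inf
restricts nothing, −inf everything. The validation metric is rMAE =
mean |map − ref| / mean ref, computed on stocks (t) for biomass so large
units weigh as much as they contain.

## Known limitations

* The bias adjustment corrects systematic error only; pixel-level random
  error passes through untouched.
* Calibrated thresholds are as good as the restriction statistics; with
  overlapping restrictions the union understates the sum of the parts by
  construction.
* The SoEF trend extension assumes linearity over the reporting span.
* The young-stand density term treats net afforestation as a single
  cohort; age-structured dynamics are outside scope.
* Minimum-mapping-unit enforcement and reprojection are not implemented;
  inputs are assumed co-registered.
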