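"""Cover-biomass model fitting, zero-biomass infill and bias adjustment."""

import numpy as np
import pytest

from forestharm.biomass_map import (
    bias_adjust_map,
    fit_cover_model,
    infill_zero_biomass,
)
from forestharm.raster import Grid, zonal_stats


def _flat_scene(n=40, zone_id=1):
    zones = Grid(np.full((n, n), zone_id, dtype=int), nodata=0)
    mask = zones.like(np.ones((n, n), dtype=np.uint8), nodata=255)
    return zones, mask


class TestFitCoverModel:
    def test_noiseless_linear_recovery(self, rng):
        zones, mask = _flat_scene()
        cover = zones.like(rng.uniform(0, 100, zones.shape))
        biomass = zones.like(2.0 * cover.values)
        m = fit_cover_model(biomass, cover, mask, zones, {1})
        assert m.slope == pytest.approx(2.0, abs=1e-9)
        assert m.intercept == pytest.approx(0.0, abs=1e-7)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_cover_rejected(self):
        zones, mask = _flat_scene(20)
        cover = zones.like(np.full(zones.shape, 50.0))
        biomass = zones.like(np.full(zones.shape, 100.0))
        with pytest.raises(ValueError, match="variance"):
            fit_cover_model(biomass, cover, mask, zones, {1})

    def test_insufficient_pixels_rejected(self):
        zones, mask = _flat_scene(8)  # 64 < default minimum of 100
        cover = zones.like(np.linspace(0, 100, 64).reshape(8, 8))
        biomass = zones.like(2 * cover.values + 1)
        with pytest.raises(ValueError, match="eligible"):
            fit_cover_model(biomass, cover, mask, zones, {1})

    def test_noisy_slope_recovery_within_sampling_error(self, rng):
        """n = 5000, Gaussian noise sd 5: the OLS slope estimate falls
        within +/-0.05 of the true 1.5 (sampling-theory bound)."""
        n = 5000
        side = int(np.ceil(np.sqrt(n)))
        zones, mask = _flat_scene(side)
        cover = zones.like(rng.uniform(0, 100, zones.shape))
        biomass = zones.like(
            np.clip(1.5 * cover.values + rng.normal(0, 5, zones.shape), 0.01, None)
        )
        m = fit_cover_model(biomass, cover, mask, zones, {1})
        assert m.slope == pytest.approx(1.5, abs=0.05)
        assert m.n_pixels >= n

    def test_zero_biomass_pixels_excluded_from_fit(self, rng):
        zones, mask = _flat_scene(20)
        cover = zones.like(rng.uniform(10, 90, zones.shape))
        vals = 2.0 * cover.values
        vals[:5, :] = 0.0  # the pixels to be infilled must not bias the fit
        m = fit_cover_model(zones.like(vals), cover, mask, zones, {1})
        assert m.slope == pytest.approx(2.0, abs=1e-9)


class TestInfill:
    def test_identity_without_zero_pixels(self, rng):
        zones, mask = _flat_scene(20)
        cover = zones.like(rng.uniform(10, 90, zones.shape))
        biomass = zones.like(2.0 * cover.values + 1.0)
        m = fit_cover_model(biomass, cover, mask, zones, {1}, min_pixels=10)
        out = infill_zero_biomass(biomass, m, mask, cover, zones, {1})
        assert np.array_equal(out.values, biomass.values)

    def test_direct_prediction_on_zero_pixel(self, rng):
        zones, mask = _flat_scene(20)
        cover = zones.like(rng.uniform(10, 90, zones.shape))
        cover.values[0, 0] = 50.0
        biomass = zones.like(2.0 * cover.values)
        biomass.values[0, 0] = 0.0
        m = fit_cover_model(biomass, cover, mask, zones, {1}, min_pixels=10)
        out = infill_zero_biomass(biomass, m, mask, cover, zones, {1})
        assert out.values[0, 0] == pytest.approx(100.0, rel=1e-6)
        untouched = np.ones(zones.shape, bool)
        untouched[0, 0] = False
        assert np.array_equal(out.values[untouched], biomass.values[untouched])

    def test_region_mismatch_rejected(self, rng):
        zones, mask = _flat_scene(20)
        cover = zones.like(rng.uniform(10, 90, zones.shape))
        biomass = zones.like(2.0 * cover.values + 1)
        m = fit_cover_model(biomass, cover, mask, zones, {1}, min_pixels=10)
        with pytest.raises(ValueError, match="region"):
            infill_zero_biomass(biomass, m, mask, cover, zones, {2})

    def test_patch_recovery_on_synthetic_scene(self, default_scene):
        """Infilling the carved zero patch recovers the (biased) truth mean
        of the patch within 10%."""
        sc = default_scene
        region = [sc.zero_patch_zone]
        m = fit_cover_model(
            sc.agb_observed, sc.tree_cover, sc.forest_truth, sc.zone_map, region
        )
        out = infill_zero_biomass(
            sc.agb_observed, m, sc.forest_truth, sc.tree_cover, sc.zone_map,
            region,
        )
        patch = np.asarray(sc.zero_patch.values, bool)
        assert patch.any()
        bias = sc.bias_factors[sc.zero_patch_zone]
        truth_mean = (np.asarray(sc.agb_truth.values)[patch] * bias).mean()
        infill_mean = np.asarray(out.values)[patch].mean()
        assert infill_mean == pytest.approx(truth_mean, rel=0.10)


class TestBiasAdjust:
    def test_ratio_definition(self):
        zones, mask = _flat_scene(10)
        biomass = zones.like(np.full(zones.shape, 80.0))
        out, factors = bias_adjust_map(biomass, zones, mask, {1: 100.0})
        assert factors.loc[1, "factor"] == pytest.approx(1.25)
        assert out.values.mean() == pytest.approx(100.0)

    def test_identity_when_reference_matches(self, rng):
        zones, mask = _flat_scene(10)
        biomass = zones.like(rng.uniform(50, 150, zones.shape))
        ref = float(biomass.values.mean())
        out, factors = bias_adjust_map(biomass, zones, mask, {1: ref})
        assert factors.loc[1, "factor"] == pytest.approx(1.0)
        assert np.allclose(out.values, biomass.values)

    def test_all_zone_means_match_reference_exactly(self, default_scene):
        """Zonal-mean oracle: every adjusted zone mean equals its reference
        within 1e-9 relative."""
        sc = default_scene
        ref = {
            int(r["zone"]): r["agb_t_ha"]
            for _, r in sc.truth_stats.reset_index().iterrows()
        }
        out, factors = bias_adjust_map(
            sc.agb_observed, sc.zone_map, sc.forest_truth, ref
        )
        zs = zonal_stats(out, sc.zone_map, mask=sc.forest_truth)
        for z, r in ref.items():
            assert zs.loc[z, "mean"] == pytest.approx(r, rel=1e-9)
        assert (out.values >= 0).all()

    def test_zero_mean_zone_flagged(self):
        zones, mask = _flat_scene(10)
        biomass = zones.like(np.zeros(zones.shape))
        out, factors = bias_adjust_map(biomass, zones, mask, {1: 50.0})
        assert factors.loc[1, "flag"] == "zero_mean"
        assert np.array_equal(out.values, biomass.values)

    def test_missing_reference_passthrough(self, rng):
        zones, mask = _flat_scene(10)
        biomass = zones.like(rng.uniform(1, 10, zones.shape))
        out, factors = bias_adjust_map(biomass, zones, mask, {})
        assert factors.loc[1, "flag"] == "no_reference"
        assert np.array_equal(out.values, biomass.values)

    def test_infill_commutes_with_scalar_adjustment(self, default_scene):
        """For fixed per-zone factors, scaling after infill equals
        infilling the pre-scaled map with a same-scaled model: the
        adjustment is a per-zone scalar multiply."""
        from forestharm.biomass_map import CoverBiomassModel

        sc = default_scene
        region = [sc.zero_patch_zone]
        ref = {
            int(r["zone"]): r["agb_t_ha"]
            for _, r in sc.truth_stats.reset_index().iterrows()
        }
        m = fit_cover_model(
            sc.agb_observed, sc.tree_cover, sc.forest_truth, sc.zone_map, region
        )
        infilled = infill_zero_biomass(
            sc.agb_observed, m, sc.forest_truth, sc.tree_cover, sc.zone_map,
            region,
        )
        adj1, f1 = bias_adjust_map(infilled, sc.zone_map, sc.forest_truth, ref)
        # reverse order with the *same* factors applied by hand first
        zones = np.asarray(sc.zone_map.values)
        forest = np.asarray(sc.forest_truth.values, bool)
        scaled = np.asarray(sc.agb_observed.values, float).copy()
        for z, k in f1["factor"].items():
            scaled[forest & (zones == z)] *= k
        k = f1.loc[sc.zero_patch_zone, "factor"]
        m_scaled = CoverBiomassModel(
            intercept=m.intercept * k, slope=m.slope * k,
            calibration_region=m.calibration_region,
            n_pixels=m.n_pixels, r2=m.r2,
        )
        adj2 = infill_zero_biomass(
            sc.agb_observed.like(scaled), m_scaled, sc.forest_truth,
            sc.tree_cover, sc.zone_map, region,
        )
        assert np.allclose(adj1.values, adj2.values, rtol=1e-9, equal_nan=True)
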