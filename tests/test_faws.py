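"""kNDVI, restriction-threshold calibration and FAWS mask construction."""

import numpy as np
import pytest

from forestharm.faws import (
    Direction,
    RestrictionRule,
    build_fnaws_mask,
    calibrate_threshold,
    compute_kndvi,
    faws_biomass_map,
    inherit_thresholds,
    restricted_mask,
)
from forestharm.raster import Grid


def _forest(n=32):
    return Grid(np.ones((n, n), dtype=np.uint8), nodata=255)


class TestKndvi:
    def test_zero_difference_gives_zero(self):
        g = Grid(np.full((4, 4), 0.3))
        assert np.allclose(compute_kndvi(g, g).values, 0.0)

    def test_closed_form_value(self):
        nir = Grid(np.full((2, 2), 0.5))
        red = Grid(np.full((2, 2), 0.2))
        out = compute_kndvi(nir, red, sigma=0.15)
        assert out.values[0, 0] == pytest.approx(np.tanh(1.0), rel=1e-12)

    def test_monotone_in_band_difference(self, rng):
        red = Grid(np.full((10, 10), 0.1))
        d1 = rng.uniform(0, 0.4, (10, 10))
        d2 = d1 + rng.uniform(0, 0.3, (10, 10))
        k1 = compute_kndvi(Grid(0.1 + d1), red).values
        k2 = compute_kndvi(Grid(0.1 + d2), red).values
        assert (k2 >= k1).all()
        assert ((k1 >= 0) & (k1 < 1)).all()

    def test_bad_sigma_rejected(self):
        g = Grid(np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            compute_kndvi(g, g, sigma=0.0)


def _brute_force_threshold(values, n_target, direction):
    """Exhaustive sweep over every unique candidate threshold."""
    best = None
    for t in np.unique(values):
        if direction is Direction.ABOVE:
            c = int((values > t).sum())
        elif direction is Direction.BELOW:
            c = int((values <= t).sum())
        else:
            c = int((values == t).sum())
        key = (abs(c - n_target), c)
        if best is None or key < best[0]:
            best = (key, t, c)
    if direction is Direction.ABOVE:
        c = values.size
        key = (abs(c - n_target), c)
        if key < best[0]:
            best = (key, -np.inf, c)
    return best[1], best[2]


class TestCalibrateThreshold:
    def test_uniform_slope_grid_hits_percentile(self, rng):
        vals = rng.uniform(0, 50, 1000)
        grid = Grid(vals.reshape(40, 25))
        rule = RestrictionRule("slope", grid)
        forest = Grid(np.ones((40, 25), np.uint8), nodata=255)
        calibrate_threshold(rule, forest, 100.0)
        t = rule.thresholds[0]
        assert t == pytest.approx(np.quantile(vals, 0.9), abs=0.5)
        restricted = int((vals > t).sum())
        assert abs(restricted - 100) <= 1

    @pytest.mark.parametrize("direction", list(Direction))
    def test_matches_brute_force_sweep(self, rng, direction):
        """Calibrated thresholds reproduce an exhaustive sweep's optimum."""
        for _ in range(5):
            if direction is Direction.EQUAL:
                vals = rng.integers(0, 2, 400).astype(float)
            else:
                vals = np.round(rng.uniform(0, 30, 400), 1)  # forced ties
            grid = Grid(vals.reshape(20, 20))
            rule = RestrictionRule("x", grid, direction=direction)
            target = float(rng.integers(1, 399))
            if direction is Direction.EQUAL:
                target = float((vals == 1).sum())
            calibrate_threshold(rule, Grid(np.ones((20, 20), np.uint8), nodata=255), target)
            t_ref, c_ref = _brute_force_threshold(vals, target, direction)
            got = restricted_mask(rule, Grid(np.ones((20, 20), np.uint8), nodata=255))
            assert int(got.values.sum()) == c_ref

    def test_binary_layer_selects_protected_class(self, rng):
        vals = (rng.random((20, 20)) > 0.7).astype(float)
        rule = RestrictionRule("protected_area", Grid(vals))
        forest = Grid(np.ones((20, 20), np.uint8), nodata=255)
        calibrate_threshold(rule, forest, float(vals.sum()))
        assert rule.thresholds[0] == 1.0
        assert int(restricted_mask(rule, forest).values.sum()) == int(vals.sum())

    def test_zero_target_restricts_nothing(self, rng):
        rule = RestrictionRule("slope", Grid(rng.uniform(0, 50, (10, 10))))
        forest = Grid(np.ones((10, 10), np.uint8), nodata=255)
        calibrate_threshold(rule, forest, 0.0)
        assert int(restricted_mask(rule, forest).values.sum()) == 0

    def test_full_target_restricts_everything(self, rng):
        rule = RestrictionRule("slope", Grid(rng.uniform(0, 50, (10, 10))))
        forest = Grid(np.ones((10, 10), np.uint8), nodata=255)
        calibrate_threshold(rule, forest, 100.0)
        assert int(restricted_mask(rule, forest).values.sum()) == 100

    def test_regional_split_meets_each_target(self, rng):
        """North/south calibration regions independently match their areas."""
        vals = rng.uniform(0, 1, (20, 20))
        regions = np.zeros((20, 20), dtype=int)
        regions[10:, :] = 1
        rule = RestrictionRule(
            "productivity", Grid(vals),
            calibration_regions=Grid(regions, nodata=-1),
        )
        forest = Grid(np.ones((20, 20), np.uint8), nodata=255)
        calibrate_threshold(rule, forest, {0: 30.0, 1: 70.0})
        got = np.asarray(restricted_mask(rule, forest).values, bool)
        assert abs(int(got[:10].sum()) - 30) <= 1
        assert abs(int(got[10:].sum()) - 70) <= 1


class TestFnawsMask:
    def test_no_rules_gives_full_faws(self):
        forest = Grid((np.arange(100).reshape(10, 10) % 3 == 0).astype(np.uint8), nodata=255)
        fnaws, faws = build_fnaws_mask([], forest)
        assert fnaws.values.sum() == 0
        assert np.array_equal(faws.values, forest.values)

    def test_union_of_disjoint_and_overlapping_restrictions(self, rng):
        forest = Grid(np.ones((10, 10), np.uint8), nodata=255)
        a = np.zeros((10, 10)); a[:5, :] = 1.0
        b = np.zeros((10, 10)); b[5:, :] = 1.0
        ra = RestrictionRule("protected_area", Grid(a), thresholds={0: 1.0})
        rb = RestrictionRule("protected_species", Grid(b), thresholds={0: 1.0})
        fnaws, faws = build_fnaws_mask([ra, rb], forest)
        assert fnaws.values.sum() == 100  # disjoint: areas add
        fnaws2, _ = build_fnaws_mask([ra, ra], forest)
        assert fnaws2.values.sum() == 50  # full overlap: union, not sum

    def test_faws_fnaws_partition_forest(self, default_scene):
        from forestharm.pipeline import build_restriction_rules

        sc = default_scene
        rules = build_restriction_rules(sc, sc.restriction_stats)
        fnaws, faws = build_fnaws_mask(rules, sc.forest_truth)
        f = np.asarray(sc.forest_truth.values, bool)
        assert np.array_equal(
            np.asarray(fnaws.values, bool) | np.asarray(faws.values, bool), f
        )
        assert not (
            np.asarray(fnaws.values, bool) & np.asarray(faws.values, bool)
        ).any()

    def test_per_rule_calibrated_area_matches_statistic(self, default_scene):
        """Each restriction independently reproduces its reference area
        within one pixel."""
        from forestharm.pipeline import build_restriction_rules

        sc = default_scene
        rules = build_restriction_rules(sc, sc.restriction_stats)
        countries = sorted(set(sc.country_of_zone.values()))
        cidx = {cc: i for i, cc in enumerate(countries)}
        for rule in rules:
            got = restricted_mask(rule, sc.forest_truth)
            regions = np.asarray(rule.calibration_regions.values)
            sub = sc.restriction_stats[sc.restriction_stats["rule"] == rule.name]
            for _, row in sub.iterrows():
                rid = cidx[row["country"]] + len(countries) * int(row["region"])
                area = float(
                    np.asarray(got.values, bool)[regions == rid].sum()
                ) * sc.zone_map.pixel_area
                assert abs(area - row["area_ha"]) <= sc.zone_map.pixel_area


class TestFawsBiomass:
    def test_partition_of_stock(self, default_scene):
        from forestharm.pipeline import build_restriction_rules

        sc = default_scene
        rules = build_restriction_rules(sc, sc.restriction_stats)
        fnaws, faws = build_fnaws_mask(rules, sc.forest_truth)
        baws_map = faws_biomass_map(sc.agb_truth, faws)
        bnaws_map = faws_biomass_map(sc.agb_truth, fnaws)
        total = np.asarray(sc.agb_truth.values)[
            np.asarray(sc.forest_truth.values, bool)
        ].sum()
        got = np.nansum(baws_map.values) + np.nansum(bnaws_map.values)
        assert got == pytest.approx(total, rel=1e-12)

    def test_empty_faws_all_nodata(self):
        agb = Grid(np.full((5, 5), 10.0))
        faws = Grid(np.zeros((5, 5), np.uint8), nodata=255)
        out = faws_biomass_map(agb, faws)
        assert np.isnan(out.values).all()


class TestInheritThresholds:
    def test_single_donor_copy_and_mean_of_two(self):
        calib = {
            "AA": {"slope": {0: 30.0}},
            "BB": {"slope": {0: 25.0}},
            "CC": {"slope": {0: 35.0}},
        }
        out, prov = inherit_thresholds("XX", {"XX": ["AA"]}, calib)
        assert out["slope"][0] == 30.0
        out2, prov2 = inherit_thresholds("XX", {"XX": ["BB", "CC"]}, calib)
        assert out2["slope"][0] == 30.0
        assert (prov2["uncertainty"] == 3).all()

    def test_no_donor_rejected(self):
        with pytest.raises(ValueError):
            inherit_thresholds("XX", {"XX": ["ZZ"]}, {})
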