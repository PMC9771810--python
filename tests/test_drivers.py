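"""Driver analysis: HURDAT2, storm exposure, sea-level trends, panels."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

import marshchange as mc
from marshchange.drivers import LocalPlane, point_diameter_km, storm_footprint


def make_track(points):
    spec = mc.TrackSpec("AL", 1, 2007, "TEST", points=points)
    return mc.parse_hurdat2(mc.generate_hurdat([spec]))[0]


class TestParseHurdat2:
    def test_round_trip(self):
        spec = mc.TrackSpec("AL", 9, 2011, "IRENE", points=[
            ("20110821 0000", 15.0, -59.0, 45, (40, 30, 20, 50)),
            ("20110823 1200", 28.0, -89.6, 140, None),
        ])
        tracks = mc.parse_hurdat2(mc.generate_hurdat([spec]))
        assert len(tracks) == 1
        t = tracks[0]
        assert t.storm_id == "AL092011" and t.name == "IRENE"
        assert len(t.points) == 2
        assert t.points.loc[0, "max_wind_kt"] == 45
        assert t.points.loc[0, "r34_nw"] == 50

    def test_hemisphere_sign_convention(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 80, None)])
        assert t.points.loc[0, "lat"] == pytest.approx(28.0)
        assert t.points.loc[0, "lon"] == pytest.approx(-89.6)

    def test_sentinel_radii_become_missing(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 80, None)])
        assert t.points[["r34_ne", "r34_se", "r34_sw", "r34_nw"]].isna().all().all()

    def test_malformed_header_reports_line(self):
        with pytest.raises(ValueError, match="line 1"):
            mc.parse_hurdat2("not a header\n")

    def test_point_count_mismatch_warns(self):
        text = "AL012007,  TEST,  3,\n" \
               "20070901, 0000,  , HU, 28.0N,  89.6W,  80, -999,\n"
        with pytest.warns(UserWarning, match="expected 3"):
            tracks = mc.parse_hurdat2(text)
        assert len(tracks[0].points) == 1

    def test_latitude_out_of_range_rejected_by_writer(self):
        spec = mc.TrackSpec("AL", 1, 2007, "BAD",
                            points=[("20070901 0000", 95.0, 0.0, 80, None)])
        with pytest.raises(ValueError, match="latitude"):
            mc.generate_hurdat([spec])


class TestSaffirSimpson:
    @pytest.mark.parametrize("wind,cat", [
        (30, 0), (63.9, 0), (64, 1), (82.9, 1), (83, 2), (96, 3),
        (113, 4), (137, 5), (140, 5),
    ])
    def test_thresholds(self, wind, cat):
        assert mc.saffir_simpson(wind) == cat

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            mc.saffir_simpson(-1)


class TestStormFootprint:
    def test_diameter_is_twice_max_radius(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 80, (40, 30, 20, 50))])
        assert point_diameter_km(t.points.iloc[0], {}) == pytest.approx(
            2 * 50 * 1.852)

    def test_category_fallback_radius(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 100, None)])  # cat 3
        plane = LocalPlane(28.0, -89.6)
        polys = storm_footprint(t, {3: 300.0}, plane)
        assert len(polys) == 1
        # buffer radius = 150 km
        assert polys[0].bounds[2] == pytest.approx(150.0, rel=1e-3)

    def test_no_radii_no_fallback_skips_with_warning(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 100, None)])
        with pytest.warns(UserWarning, match="skipped"):
            polys = storm_footprint(t, {}, LocalPlane(28.0, -89.6))
        assert polys == []

    def test_buffer_contains_center(self):
        t = make_track([("20070901 0000", 28.0, -89.6, 80, (40, 30, 20, 50))])
        plane = LocalPlane(28.0, -89.6)
        poly = storm_footprint(t, {}, plane)[0]
        assert poly.contains(Point(plane.to_plane(-89.6, 28.0)))


class TestWatershedExposure:
    WATERSHEDS = {
        1: Polygon([(-90, 29), (-89, 29), (-89, 30), (-90, 30)]),
        2: Polygon([(-88, 29), (-87, 29), (-87, 30), (-88, 30)]),
        3: Polygon([(-86, 29), (-85, 29), (-85, 30), (-86, 30)]),
    }

    def test_track_crossing_one_watershed(self):
        t = make_track([("20070901 0000", 29.5, -89.5, 80, (30, 30, 30, 30))])
        out = mc.watershed_exposure([t], self.WATERSHEDS, mc.default_epochs())
        hit = out[out["landfall"]]
        assert list(hit["watershed"]) == [1]
        assert hit.iloc[0]["category"] == 1
        assert hit.iloc[0]["epoch"] == "2005-2009"

    def test_highest_category_wins(self):
        t1 = make_track([("20070901 0000", 29.5, -89.5, 70, (30,) * 4)])   # cat 1
        t2 = make_track([("20080901 0000", 29.5, -89.5, 100, (30,) * 4)])  # cat 3
        out = mc.watershed_exposure([t1, t2], self.WATERSHEDS, mc.default_epochs())
        rec = out.query("watershed == 1 and epoch == '2005-2009'").iloc[0]
        assert rec["category"] == 3

    def test_storm_outside_epochs_excluded(self):
        spec = mc.TrackSpec("AL", 1, 1999, "OLD",
                            points=[("19990901 0000", 29.5, -89.5, 100, (30,) * 4)])
        t = mc.parse_hurdat2(mc.generate_hurdat([spec]))[0]
        out = mc.watershed_exposure([t], self.WATERSHEDS, mc.default_epochs())
        assert not out["landfall"].any()

    def test_sub_hurricane_points_ignored(self):
        t = make_track([("20070901 0000", 29.5, -89.5, 50, (30,) * 4)])
        out = mc.watershed_exposure([t], self.WATERSHEDS, mc.default_epochs())
        assert not out["landfall"].any()
        assert (out["category"] == 0).all()

    def test_matches_brute_force_point_in_buffer(self):
        rng = np.random.default_rng(4)
        pts = [("2007090%d 0000" % (i + 1), float(29 + rng.uniform(-1, 1)),
                float(-88 + rng.uniform(-3, 3)), 90.0, (60,) * 4)
               for i in range(5)]
        t = make_track(pts)
        out = mc.watershed_exposure([t], self.WATERSHEDS, mc.default_epochs())
        plane_pts = [(p[2], p[1]) for p in pts]  # lon, lat
        r_km = 2 * 60 * 1.852 / 2
        for wid, poly in self.WATERSHEDS.items():
            # brute force on a geographic plane centred like the implementation
            all_coords = [c for pl in self.WATERSHEDS.values()
                          for c in pl.exterior.coords]
            plane = LocalPlane(np.mean([c[1] for c in all_coords]),
                               np.mean([c[0] for c in all_coords]))
            expected = any(
                Point(plane.to_plane(lon, lat)).buffer(r_km)
                .intersects(plane.polygon(poly))
                for lon, lat in plane_pts)
            got = out.query("watershed == @wid")["landfall"].any()
            assert got == expected

    def test_empty_watersheds_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mc.watershed_exposure([], {}, mc.default_epochs())


class TestDecomposition:
    def test_components_reconstruct_series(self):
        s = mc.generate_tide_series(4.0, 30.0, 5.0, 120, seed=2)
        dec = mc.decompose_monthly(s)
        ok = dec.dropna()
        np.testing.assert_allclose(ok["trend"] + ok["seasonal"] + ok["resid"],
                                   ok["msl_mm"], atol=1e-9)

    def test_linear_series_trend_slope_preserved(self):
        s = mc.generate_tide_series(7.0, 0.0, 0.0, 120, seed=0)
        dec = mc.decompose_monthly(s)
        assert mc.lslc_trend(dec) == pytest.approx(7.0, abs=1e-9)

    def test_pure_sinusoid_goes_to_seasonal(self):
        s = mc.generate_tide_series(0.0, 50.0, 0.0, 120, seed=0)
        dec = mc.decompose_monthly(s)
        ok = dec.dropna()
        assert ok["trend"].std() == pytest.approx(0.0, abs=1e-9)
        assert ok["seasonal"].abs().max() == pytest.approx(50.0, rel=1e-6)

    def test_trend_undefined_at_edges(self):
        dec = mc.decompose_monthly(mc.generate_tide_series(1, 1, 0, 60))
        assert dec["trend"].isna().iloc[:6].all()
        assert dec["trend"].isna().iloc[-6:].all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mc.generate_tide_series(1, 1, 0, 12)
        with pytest.raises(ValueError):
            mc.decompose_monthly(pd.DataFrame(
                {"year": [2000], "month": [1], "msl_mm": [0.0]}))


class TestLslc:
    def test_constant_series_zero_trend(self):
        s = mc.generate_tide_series(0.0, 0.0, 0.0, 60)
        assert mc.lslc_trend(mc.decompose_monthly(s)) == pytest.approx(0.0, abs=1e-9)

    def test_station_averaging(self):
        a = mc.generate_tide_series(4.0, 20.0, 0.0, 60).assign(
            station="A", watershed=1)
        b = mc.generate_tide_series(6.0, 20.0, 0.0, 60).assign(
            station="B", watershed=1)
        tide = pd.concat([a, b])
        out = mc.watershed_lslc(tide, [mc.EpochSpec("2000-2004", 2000, 2004, (8, 9))])
        assert out.iloc[0]["lslc_mm_yr"] == pytest.approx(5.0, abs=1e-6)
        assert out.iloc[0]["n_stations"] == 2

    def test_equivariance_under_added_trend(self):
        s = mc.generate_tide_series(3.0, 40.0, 0.0, 120, seed=1)
        shifted = s.copy()
        shifted["msl_mm"] = shifted["msl_mm"] + 2.0 * np.arange(len(s)) / 12.0
        t0 = mc.lslc_trend(mc.decompose_monthly(s))
        t1 = mc.lslc_trend(mc.decompose_monthly(shifted))
        assert t1 - t0 == pytest.approx(2.0, abs=1e-9)

    def test_insufficient_months_gives_nan(self):
        dec = mc.decompose_monthly(mc.generate_tide_series(1, 1, 0, 60))
        missing = mc.lslc_trend(dec, mc.EpochSpec("x", 1990, 1994, (8, 9)))
        assert np.isnan(missing)


class TestPanel:
    def test_exact_recovery_zero_noise(self):
        panel = mc.generate_panel_covariates(
            30, 4, {"hurricane_cat": 10.0, "lslc": -2.0}, 0.0, seed=8)
        fit = mc.fit_panel(panel)
        assert fit.coefficients.loc["hurricane_cat", "coef"] == pytest.approx(
            10.0, abs=1e-8)
        assert fit.coefficients.loc["lslc", "coef"] == pytest.approx(-2.0, abs=1e-8)
        assert fit.coefficients.loc["urbanization", "coef"] == pytest.approx(
            0.0, abs=1e-8)

    def test_constant_shift_changes_no_covariate(self):
        panel = mc.generate_panel_covariates(20, 4, {"lslc": 1.5}, 0.3, seed=2)
        shifted = panel.copy()
        shifted["response"] = shifted["response"] + 100.0
        c0 = mc.fit_panel(panel).coefficients["coef"]
        c1 = mc.fit_panel(shifted).coefficients["coef"]
        np.testing.assert_allclose(c0, c1, atol=1e-8)

    def test_missing_rows_dropped_and_counted(self):
        panel = mc.generate_panel_covariates(20, 4, {"lslc": 1.0}, 0.1, seed=5)
        panel.loc[3, "lslc"] = np.nan
        fit = mc.fit_panel(panel)
        assert fit.n_dropped == 1 and fit.n_rows == len(panel) - 1

    def test_collinear_design_raises(self):
        panel = mc.generate_panel_covariates(20, 4, {"lslc": 1.0}, 0.1, seed=6)
        panel["buffer_gain"] = panel["buffer_loss"]
        with pytest.raises(ValueError, match="collinear"):
            mc.fit_panel(panel)

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError):
            mc.generate_panel_covariates(2, 2, {"lslc": 1.0}, 0.1)

    def test_permuted_response_pvalues_roughly_uniform(self):
        """Type-I control: permuting the response kills the signal."""
        rng = np.random.default_rng(10)
        pvals = []
        for rep in range(40):
            panel = mc.generate_panel_covariates(
                15, 4, {"hurricane_cat": 5.0}, 0.5, seed=100 + rep)
            panel["response"] = rng.permutation(panel["response"].to_numpy())
            fit = mc.fit_panel(panel)
            pvals.append(fit.coefficients.loc["hurricane_cat", "p"])
        # mean of uniform p-values ~ 0.5 +- 3*sd
        assert abs(np.mean(pvals) - 0.5) < 3 * (1 / np.sqrt(12 * 40))
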