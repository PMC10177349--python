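"""Covariate engineering: distances, aspect, IDW, wind chill, VIF, assembly."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from grazedrivers import (
    build_grid,
    compute_aspect,
    interpolate_ndvi,
    join_weather,
    near_distance,
    sample_raster,
    vif_filter,
    wind_chill,
)
from grazedrivers.raster import Raster


def seg_dist_oracle(p, a, b):
    """Point-to-segment distance by projection clamping (independent of shapely)."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0, 1)
    return float(np.linalg.norm(p - (a + t * ab)))


class TestNearDistance:
    def test_single_tree(self):
        assert near_distance([3.0], [4.0], np.array([[0.0, 0.0]]))[0] == pytest.approx(5.0)

    def test_point_on_fence_segment(self):
        fence = LineString([(0, 0), (10, 0)])
        assert near_distance([5.0], [0.0], fence)[0] == 0.0

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty feature set"):
            near_distance([0.0], [0.0], np.empty((0, 2)))

    def test_matches_min_over_segments_oracle(self, rng):
        segs = [LineString(rng.uniform(0, 100, (2, 2))) for _ in range(20)]
        pts = rng.uniform(0, 100, (500, 2))
        got = near_distance(pts[:, 0], pts[:, 1], segs)
        for i in range(len(pts)):
            oracle = min(
                seg_dist_oracle(pts[i], np.asarray(s.coords[0]), np.asarray(s.coords[1]))
                for s in segs
            )
            assert got[i] == pytest.approx(oracle, abs=1e-9)

    def test_rigid_translation_invariance(self, rng):
        pts = rng.uniform(0, 50, (50, 2))
        trees = rng.uniform(0, 50, (10, 2))
        d0 = near_distance(pts[:, 0], pts[:, 1], trees)
        d1 = near_distance(pts[:, 0] + 1234.5, pts[:, 1] - 987.0,
                           trees + np.array([1234.5, -987.0]))
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestSampleRaster:
    def test_constant_raster(self, rng):
        r = Raster(0, 0, 5, np.full((4, 4), 7.25))
        e, n = rng.uniform(0, 20, (2, 50))
        np.testing.assert_array_equal(sample_raster(e, n, r), 7.25)

    def test_half_open_cell_edges(self):
        r = Raster(0, 0, 5, np.arange(4).reshape(2, 2).astype(float))
        assert sample_raster(5.0, 0.0, r) == 1.0  # on the shared edge -> right cell

    def test_matches_index_arithmetic_oracle(self, rng):
        vals = rng.normal(size=(10, 8))
        r = Raster(100, 200, 2.5, vals)
        e = rng.uniform(100, 119.99, 200)
        n = rng.uniform(200, 224.99, 200)
        got = sample_raster(e, n, r)
        oracle = vals[((n - 200) // 2.5).astype(int), ((e - 100) // 2.5).astype(int)]
        np.testing.assert_array_equal(got, oracle)

    def test_outside_extent_raises(self):
        r = Raster(0, 0, 5, np.zeros((2, 2)))
        with pytest.raises(ValueError, match="outside raster extent"):
            sample_raster(11.0, 0.0, r)


class TestAspect:
    def test_plane_dipping_due_south(self):
        # elevation rises northward -> downslope azimuth 180 deg everywhere
        z = np.arange(10)[:, None] * np.ones((10, 10))
        asp = compute_aspect(Raster(0, 0, 5, z))
        np.testing.assert_allclose(asp.values, 180.0)

    def test_plane_dipping_due_east(self):
        z = -np.arange(10)[None, :] * np.ones((10, 10))
        asp = compute_aspect(Raster(0, 0, 5, z))
        np.testing.assert_allclose(asp.values, 90.0)

    def test_flat_raster_all_flagged(self):
        asp = compute_aspect(Raster(0, 0, 5, np.full((5, 5), 42.0)))
        assert np.isnan(asp.values).all()

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            compute_aspect(Raster(0, 0, 5, np.zeros((2, 5))))

    def test_interior_matches_independent_horn_stencil(self, rng):
        from scipy.ndimage import gaussian_filter
        z = gaussian_filter(rng.normal(size=(20, 20)), 3) * 50
        s = 5.0
        asp = compute_aspect(Raster(0, 0, s, z)).values
        for r in range(1, 19):
            for c in range(1, 19):
                dzdx = ((z[r + 1, c + 1] + 2 * z[r, c + 1] + z[r - 1, c + 1])
                        - (z[r + 1, c - 1] + 2 * z[r, c - 1] + z[r - 1, c - 1])) / (8 * s)
                dzdy = ((z[r + 1, c - 1] + 2 * z[r + 1, c] + z[r + 1, c + 1])
                        - (z[r - 1, c - 1] + 2 * z[r - 1, c] + z[r - 1, c + 1])) / (8 * s)
                expected = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360
                assert asp[r, c] == pytest.approx(expected, abs=1e-6)


class TestInterpolateNdvi:
    @pytest.fixture
    def spec(self, square_100m):
        return build_grid(square_100m, 5.0)

    def test_constant_samples_give_constant_surface(self, spec, rng):
        pts = rng.uniform(0, 100, (10, 2))
        samples = pd.DataFrame({"easting": pts[:, 0], "northing": pts[:, 1], "ndvi": 0.25})
        out = interpolate_ndvi(samples, spec)
        np.testing.assert_allclose(out.values[spec.mask], 0.25)

    def test_exact_at_coincident_cell_center(self, spec):
        samples = pd.DataFrame(
            {"easting": [2.5, 50.0, 90.0], "northing": [2.5, 50.0, 10.0],
             "ndvi": [0.11, 0.3, 0.2]}
        )
        out = interpolate_ndvi(samples, spec)
        assert out.values[0, 0] == 0.11  # cell (0,0) centre is exactly (2.5, 2.5)

    def test_matches_brute_force_idw_oracle(self, spec, rng):
        pts = rng.uniform(0, 100, (15, 2))
        vals = rng.uniform(0.1, 0.4, 15)
        samples = pd.DataFrame({"easting": pts[:, 0], "northing": pts[:, 1], "ndvi": vals})
        out = interpolate_ndvi(samples, spec, power=2.0)
        for r, c in [(0, 0), (3, 7), (19, 19), (10, 2)]:
            cx, cy = (c + 0.5) * 5.0, (r + 0.5) * 5.0
            d = np.sqrt((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2)
            w = d ** -2.0
            assert out.values[r, c] == pytest.approx(np.sum(w * vals) / np.sum(w), abs=1e-9)

    def test_bounded_by_sample_range(self, spec, rng):
        pts = rng.uniform(0, 100, (25, 2))
        vals = rng.uniform(0.1, 0.4, 25)
        samples = pd.DataFrame({"easting": pts[:, 0], "northing": pts[:, 1], "ndvi": vals})
        out = interpolate_ndvi(samples, spec)
        assert np.nanmin(out.values) >= vals.min() - 1e-12
        assert np.nanmax(out.values) <= vals.max() + 1e-12

    def test_too_few_samples_rejected(self, spec):
        samples = pd.DataFrame({"easting": [1, 2], "northing": [1, 2], "ndvi": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 3"):
            interpolate_ndvi(samples, spec)


class TestWindChill:
    def test_body_temperature_no_wind_no_rain(self):
        # at T=40 the gradient term vanishes: C = 481 exactly
        assert wind_chill(40.0, 0.0, 0.0) == pytest.approx(481.0)

    def test_closed_form_reevaluation(self):
        T, v, R = 10.0, 3.0, 0.0
        expected = (11.7 + 3.1 * np.sqrt(v)) * (40 - T) + 481 + 418 * (1 - np.exp(-0.04 * R))
        assert wind_chill(T, v, R) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_each_input(self):
        base = wind_chill(10.0, 3.0, 1.0)
        assert wind_chill(5.0, 3.0, 1.0) > base  # colder -> more chill
        assert wind_chill(10.0, 6.0, 1.0) > base  # windier -> more chill
        assert wind_chill(10.0, 3.0, 5.0) > base  # wetter -> more chill

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wind_chill(np.nan, 0.0, 0.0)
        with pytest.raises(ValueError):
            wind_chill(10.0, -1.0, 0.0)


class TestJoinWeather:
    @pytest.fixture
    def weather(self, trial_start):
        times = pd.date_range(trial_start, periods=24, freq="h")
        return pd.DataFrame(
            {"timestamp": times, "temp_c": np.arange(24.0), "rain_mm": 0.5, "wind_ms": 2.0}
        )

    def test_floor_to_hour_join(self, weather, trial_start):
        rows = pd.DataFrame({"timestamp": [trial_start + pd.Timedelta("10h30min")]})
        out = join_weather(rows, weather)
        assert out["T"].iloc[0] == 10.0

    def test_gap_in_series_raises(self, weather, trial_start):
        rows = pd.DataFrame({"timestamp": [trial_start + pd.Timedelta("30h")]})
        with pytest.raises(ValueError, match="does not cover"):
            join_weather(rows, weather)

    def test_random_rows_match_merge_oracle(self, weather, trial_start, rng):
        offs = rng.uniform(0, 24 * 3600 - 1, 100)
        rows = pd.DataFrame({"timestamp": trial_start + pd.to_timedelta(offs, unit="s")})
        out = join_weather(rows, weather)
        np.testing.assert_array_equal(out["T"], (offs // 3600).astype(float))
        np.testing.assert_allclose(out["WC"], wind_chill(out["T"], 2.0, 0.5))


class TestVifFilter:
    def test_orthogonal_columns_all_retained(self, rng):
        tab = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        retained, log = vif_filter(tab)
        assert retained == list("abcd")
        assert (log["vif"] < 1.1).all()

    def test_exact_collinearity_dropped_first(self, rng):
        x1, x2 = rng.normal(size=(2, 300))
        tab = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        retained, _ = vif_filter(tab)
        assert len(retained) == 2
        final_vifs = _explicit_vifs(tab[retained])
        assert max(final_vifs.values()) < 5

    def test_correlated_pair_matches_textbook_oracle(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x1 = z + 0.1 * rng.normal(size=n)
        x2 = z + 0.1 * rng.normal(size=n)  # rho ~ 0.98 with x1
        x3 = rng.normal(size=n)
        tab = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        _, log = vif_filter(tab, threshold=np.inf)
        oracle = _explicit_vifs(tab)
        for col, v in oracle.items():
            got = log.loc[log["column"] == col, "vif"].iloc[0]
            assert got == pytest.approx(v, rel=1e-6)
        assert oracle["x1"] > 5  # the engineered near-collinear pair

    def test_constant_column_rejected(self, rng):
        tab = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            vif_filter(tab)

    def test_removal_is_deterministic(self, rng):
        tab = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("edcba"))
        tab["f"] = tab["a"] + tab["b"]
        r1, _ = vif_filter(tab)
        r2, _ = vif_filter(tab.copy())
        assert r1 == r2


def _explicit_vifs(tab: pd.DataFrame) -> dict:
    """Textbook VIF via explicit least-squares regression (numpy only)."""
    out = {}
    for col in tab.columns:
        y = tab[col].to_numpy(float)
        X = tab.drop(columns=col).to_numpy(float)
        X = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1 / (1 - r2)
    return out


class TestAssembleModelTable:
    def test_columns_match_independent_recomputation(self, ip_like_bundle):
        from grazedrivers.covariates import PREDICTORS, compute_aspect

        b = ip_like_bundle
        tab, landscape = b["table"], b["landscape"]
        assert list(tab.columns[:13]) == PREDICTORS + ["lri"]
        sub = tab.sample(50, random_state=0)
        aspect = compute_aspect(landscape.elevation)
        for _, row in sub.iterrows():
            e, n = row["EA"], row["NO"]
            d_tree = min(np.hypot(*(np.asarray(t) - [e, n])) for t in landscape.trees)
            assert row["NT"] == pytest.approx(d_tree, abs=1e-9)
            d_trough = min(np.hypot(*(np.asarray(t) - [e, n])) for t in landscape.troughs)
            assert row["NW"] == pytest.approx(d_trough, abs=1e-9)
            assert row["NDVI"] == pytest.approx(landscape.ndvi.sample(e, n))
            assert row["EL"] == pytest.approx(landscape.elevation.sample(e, n))
            assert row["AS"] == pytest.approx(aspect.sample(e, n))

    def test_every_row_has_twelve_predictors_and_target(self, ip_like_bundle):
        from grazedrivers.covariates import PREDICTORS

        tab = ip_like_bundle["table"]
        assert not tab[PREDICTORS + ["lri"]].isna().any().any()
        rep = ip_like_bundle["table_report"]
        assert rep["n_rows"] + rep["dropped_no_ndvi"] + rep["dropped_no_elevation"] >= rep["n_rows"]
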