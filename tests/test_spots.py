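import numpy as np
import pytest
from scipy import ndimage

from beanclim.raster import AreaMask, GridRaster, haversine_km
from beanclim.spots import (CATEGORY_CODES, classify_spots,
                            classify_yield_change, getis_ord_local,
                            kernel_density_mask, mean_surface,
                            robust_rms_scale, select_site_pixels,
                            yield_change)


def grid(values, cell=0.009, origin=(-86.0, 1.0), nodata=-9999.0):
    return GridRaster(np.asarray(values, dtype=float), origin, cell, nodata)


def surfaces_from(arrays):
    return {f"t{i}": grid(a) for i, a in enumerate(arrays)}


class TestYieldChange:
    def test_identical_scenarios_zero_change(self, rng):
        base = surfaces_from([rng.uniform(500, 1500, (4, 4))
                              for _ in range(8)])
        out = yield_change(base, base)
        np.testing.assert_allclose(out.delta.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.relative.values, 0.0, atol=1e-12)

    def test_percent_change(self):
        base = surfaces_from([np.full((2, 2), 1000.0)])
        fut = surfaces_from([np.full((2, 2), 620.0)])
        out = yield_change(fut, base)
        np.testing.assert_allclose(out.delta.values, -380.0)
        np.testing.assert_allclose(out.relative.values, -38.0)

    def test_matches_loop_oracle(self, rng):
        base = surfaces_from([rng.uniform(300, 2000, (3, 3))
                              for _ in range(8)])
        fut = surfaces_from([rng.uniform(300, 2000, (3, 3))
                             for _ in range(8)])
        out = yield_change(fut, base)
        for r in range(3):
            for c in range(3):
                bm = np.mean([base[k].values[r, c] for k in base])
                fm = np.mean([fut[k].values[r, c] for k in fut])
                assert out.delta.values[r, c] == pytest.approx(fm - bm)
                assert out.relative.values[r, c] == pytest.approx(
                    100.0 * (fm - bm) / bm)

    def test_treatment_mismatch_rejected(self, rng):
        base = surfaces_from([rng.random((2, 2))])
        fut = {"other": grid(rng.random((2, 2)))}
        with pytest.raises(ValueError):
            yield_change(fut, base)


def brute_force_robust_rms(x, k=3.0, max_iter=20):
    """Literal re-implementation of the iterative exclusion loop."""
    x = np.asarray(x, dtype=float)
    incl = list(range(len(x)))
    for _ in range(max_iter):
        m = sum(x[i] for i in incl) / len(incl)
        s = (sum((x[i] - m) ** 2 for i in incl) / len(incl)) ** 0.5
        new = [i for i in range(len(x)) if abs(x[i] - m) <= k * s]
        if new == incl:
            break
        incl = new
    return (x - m) / s, m, s


class TestRobustRms:
    def test_large_sample_normal(self, rng):
        x = rng.standard_normal(100_000)
        z, m, s = robust_rms_scale(x)
        # iterative 3-RMS exclusion trims the tails, so the scale settles
        # slightly below 1 for a standard normal
        assert abs(m) < 0.02
        assert 0.9 < s < 1.01
        np.testing.assert_allclose(z, (x - m) / s, atol=1e-12)

    def test_outlier_excluded_in_second_iteration(self):
        """Noise plus one gross outlier: the first pass excludes the
        outlier, the second scales by the noise alone."""
        x = np.array([-1.0, 0.0, 1.0] * 3 + [0.0, 100.0])
        z, m, s = robust_rms_scale(x)
        ze, me, se = brute_force_robust_rms(x)
        assert m == pytest.approx(me) and s == pytest.approx(se)
        np.testing.assert_allclose(z, ze, atol=1e-12)
        # after exclusion the scale is that of the small values alone
        assert m == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(np.sqrt(6.0 / 10.0), abs=1e-12)
        assert z[-1] > 10.0

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(500)
        z1, _, _ = robust_rms_scale(x)
        z2, _, _ = robust_rms_scale(-x)
        np.testing.assert_allclose(z1, -z2, atol=1e-10)

    def test_matches_brute_force_on_random(self, rng):
        for _ in range(5):
            x = rng.standard_t(df=2, size=25)
            z, m, s = robust_rms_scale(x)
            ze, me, se = brute_force_robust_rms(x)
            assert s == pytest.approx(se, rel=1e-12)
            np.testing.assert_allclose(z, ze, atol=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            robust_rms_scale(np.array([2.0, 2.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            robust_rms_scale(np.array([1.0, 2.0]))


def brute_force_gi_star(values, lons, lats, d_km):
    """Direct evaluation of the standardized Gi* formula per pixel."""
    n = len(values)
    xbar = np.mean(values)
    S = np.sqrt(np.mean(np.square(values)) - xbar ** 2)
    out = []
    for i in range(n):
        w = np.array([1.0 if haversine_km((lons[i], lats[i]),
                                          (lons[j], lats[j])) <= d_km
                      else 0.0 for j in range(n)])
        sw = w.sum()
        denom = S * np.sqrt((n * np.sum(w ** 2) - sw ** 2) / (n - 1))
        num = np.dot(w, values) - xbar * sw
        out.append(num / denom if denom > 0 else np.nan)
    return np.array(out)


class TestGetisOrd:
    def test_constant_field_all_nodata(self):
        r = grid(np.full((4, 4), 7.0))
        out = getis_ord_local(r, d_km=3.0)
        assert not out.valid.any()

    def test_cluster_centre_has_max_z(self, rng):
        vals = rng.normal(0, 0.1, (5, 5))
        vals[1:4, 1:4] += 3.0  # high cluster centred at (2, 2)
        out = getis_ord_local(grid(vals), d_km=1.5)
        r, c = np.unravel_index(np.nanargmax(out.masked()), (5, 5))
        assert (r, c) == (2, 2)

    def test_matches_brute_force(self, rng):
        r = grid(rng.normal(size=(5, 5)))
        lon, lat = r.cell_centers()
        expected = brute_force_gi_star(r.values.ravel(), lon.ravel(),
                                       lat.ravel(), d_km=2.0)
        out = getis_ord_local(r, d_km=2.0).masked().ravel()
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestClassify:
    def test_threshold_arithmetic(self):
        z = grid(np.array([[-2.5, -1.5], [1.2, 0.0]]))
        atlas = AreaMask(grid(np.ones((2, 2))))
        cls = classify_spots(z, atlas)
        assert cls.category.values[0, 0] == CATEGORY_CODES["hotspot"]
        assert cls.category.values[0, 1] == CATEGORY_CODES["adaptation"]
        assert cls.category.values[1, 0] == CATEGORY_CODES["pressure"]
        assert cls.category.values[1, 1] == CATEGORY_CODES["none"]

    def test_inclusive_boundaries(self):
        z = grid(np.array([[-2.0, -1.0], [1.0, -0.999]]))
        cls = classify_spots(z)
        assert cls.category.values[0, 0] == CATEGORY_CODES["hotspot"]
        assert cls.category.values[0, 1] == CATEGORY_CODES["adaptation"]
        assert cls.category.values[1, 0] == CATEGORY_CODES["pressure"]
        assert cls.category.values[1, 1] == CATEGORY_CODES["none"]

    def test_partition(self, rng):
        z = grid(rng.standard_normal((10, 10)))
        atlas = AreaMask(grid((rng.random((10, 10)) < 0.5).astype(float)))
        cls = classify_spots(z, atlas)
        total = sum(cls.category_mask(n).sum() for n in CATEGORY_CODES)
        assert total == z.valid.sum()

    def test_hotspots_only_inside_atlas(self):
        z = grid(np.full((3, 3), -3.0))
        atlas_vals = np.zeros((3, 3))
        atlas_vals[0, 0] = 1.0
        cls = classify_spots(z, AreaMask(grid(atlas_vals)))
        assert cls.category_mask("hotspot").sum() == 1
        assert cls.category_mask("hotspot")[0, 0]

    def test_pressure_reported_outside_atlas(self):
        z = grid(np.full((2, 2), 2.0))
        atlas = AreaMask(grid(np.zeros((2, 2))))
        cls = classify_spots(z, atlas)
        assert cls.category_mask("pressure").sum() == 4

    def test_shift_invariance_of_classification(self, rng):
        """Adding a constant to all yields leaves the categories unchanged
        (the z-field is location-scale standardized)."""
        base = surfaces_from([rng.uniform(500, 1500, (6, 6))
                              for _ in range(4)])
        fut = surfaces_from([base[k].values * rng.uniform(0.5, 1.1)
                             for k in base])
        atlas = AreaMask(grid(np.ones((6, 6))))
        c1 = classify_yield_change(yield_change(fut, base), atlas)
        shifted = {k: grid(v.values + 500.0) for k, v in fut.items()}
        base_s = {k: grid(v.values + 500.0) for k, v in base.items()}
        c2 = classify_yield_change(yield_change(shifted, base_s), atlas)
        np.testing.assert_array_equal(c1.category.values,
                                      c2.category.values)


class TestKernelDensity:
    def test_single_point_max_at_its_cell(self, unit_geom):
        lon, lat = unit_geom.cell_center(2, 3)
        mask = kernel_density_mask([(lon, lat)], unit_geom,
                                   bandwidth_km=1.0, threshold=0.99)
        assert mask.boolean[2, 3]
        assert mask.boolean.sum() == 1

    def test_two_distant_points_two_blobs(self):
        geom = GridRaster(np.zeros((20, 20)), origin=(-86.0, 1.0),
                          cell_size=0.009)
        p1 = geom.cell_center(3, 3)
        p2 = geom.cell_center(16, 16)
        mask = kernel_density_mask([p1, p2], geom, bandwidth_km=0.5,
                                   threshold=0.2)
        labels, n = ndimage.label(mask.boolean)
        assert n == 2

    def test_zero_threshold_covers_everything(self, unit_geom):
        lon, lat = unit_geom.cell_center(0, 0)
        mask = kernel_density_mask([(lon, lat)], unit_geom,
                                   bandwidth_km=2.0, threshold=0.0)
        assert mask.boolean.all()

    def test_bad_bandwidth(self, unit_geom):
        with pytest.raises(ValueError):
            kernel_density_mask([(0.0, 0.0)], unit_geom, bandwidth_km=-1.0)


class TestSiteSelection:
    @pytest.fixture
    def setting(self, rng):
        geom = GridRaster(np.zeros((9, 9)), origin=(-86.0, 1.0),
                          cell_size=0.045)  # ~5 km cells
        dem = geom.with_values(rng.uniform(300, 900, (9, 9)))
        atlas = AreaMask(geom.with_values(
            (rng.random((9, 9)) < 0.6).astype(float)))
        lon, lat = geom.cell_center(4, 4)
        community = {"name": "c", "lon": lon, "lat": lat,
                     "elevation_m": float(dem.values[4, 4])}
        return community, atlas, dem

    def test_matches_brute_force_triple_filter(self, setting):
        community, atlas, dem = setting
        got = set(select_site_pixels(community, None, atlas, dem))
        expected = set()
        for r in range(9):
            for c in range(9):
                d = haversine_km((community["lon"], community["lat"]),
                                 dem.cell_center(r, c))
                if (d <= 15.0 and atlas.boolean[r, c]
                        and abs(dem.values[r, c]
                                - community["elevation_m"]) <= 100.0):
                    expected.add((r, c))
        assert got == expected

    def test_elevation_boundary_inclusive(self, setting):
        community, atlas, dem = setting
        atlas.mask.values[:] = 1.0
        dem.values[:] = community["elevation_m"] + 100.0
        assert (4, 4) in select_site_pixels(community, None, atlas, dem)
        dem.values[:] = community["elevation_m"] + 101.0
        assert select_site_pixels(community, None, atlas, dem) == []

    def test_flat_atlas_selects_all_within_radius(self, setting):
        community, atlas, dem = setting
        atlas.mask.values[:] = 1.0
        dem.values[:] = community["elevation_m"]
        got = set(select_site_pixels(community, None, atlas, dem))
        lon, lat = dem.cell_centers()
        d = haversine_km((community["lon"], community["lat"]), (lon, lat))
        assert got == {(int(r), int(c)) for r, c in np.argwhere(d <= 15.0)}


def test_mean_surface_nodata_propagates(rng):
    a = grid(rng.random((3, 3)))
    b = grid(rng.random((3, 3)))
    b.values[1, 1] = b.nodata
    out = mean_surface([a, b])
    assert not out.valid[1, 1]
    assert out.valid.sum() == 8
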