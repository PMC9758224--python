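import numpy as np
import pandas as pd
import pytest
import xarray as xr

from pibcm.climate import (
    ClimGrid,
    coarsen,
    delta_downscale,
    depth_mask,
    ensemble_mean,
    extremes_and_range,
    extremes_frame,
    haversine_km,
    monthly_climatology,
    tps_interpolate,
)
from pibcm.errors import DegenerateDesignError, DomainError, GeometryError


def make_grid(values, lat=None, lon=None):
    """ClimGrid from a (12, nlat, nlon) array with simple center coords."""
    values = np.asarray(values, dtype=float)
    _, nlat, nlon = values.shape
    lat = np.arange(nlat) * 0.5 + 30.25 if lat is None else lat
    lon = np.arange(nlon) * 0.5 - 75.75 if lon is None else lon
    return ClimGrid(lat, lon, values)


def daily_series(values, start="2001-01-01"):
    """(time, lat, lon) DataArray from a (ntime, nlat, nlon) array."""
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=values.shape[0], freq="D")
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": times,
            "lat": np.arange(values.shape[1]) * 0.5 + 30.25,
            "lon": np.arange(values.shape[2]) * 0.5 - 75.75,
        },
    )


class TestMonthlyClimatology:
    def test_constant_series(self):
        clim = monthly_climatology(daily_series(np.full((365, 2, 2), 10.0)))
        assert np.allclose(clim.monthly_mean, 10.0)

    def test_month_indexed_series(self):
        times = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        vals = times.month.values[:, None, None] * np.ones((1, 2, 2))
        da = daily_series(vals)
        da = da.assign_coords(time=times)
        clim = monthly_climatology(da)
        for m in range(12):
            assert np.allclose(clim.monthly_mean[m], m + 1)

    def test_mean_across_years(self):
        # two Januaries at 2 and 4 degC -> January layer is 3
        times = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        vals = np.where(times.year.values == 2001, 2.0, 4.0)[:, None, None] * np.ones((1, 1, 1))
        da = daily_series(vals).assign_coords(time=times)
        clim = monthly_climatology(da)
        assert np.allclose(clim.monthly_mean, 3.0)

    def test_year_selection(self):
        times = pd.date_range("2001-01-01", "2003-12-31", freq="D")
        vals = np.where(times.year.values == 2003, 100.0, 5.0)[:, None, None] * np.ones((1, 1, 1))
        da = daily_series(vals).assign_coords(time=times)
        clim = monthly_climatology(da, years=(2001, 2002))
        assert np.allclose(clim.monthly_mean, 5.0)

    def test_all_nan_cell_is_masked(self):
        vals = np.full((365, 2, 2), 12.0)
        vals[:, 0, 0] = np.nan
        clim = monthly_climatology(daily_series(vals))
        assert not clim.valid_mask[0, 0]
        assert clim.valid_mask[1, 1]

    def test_empty_series_rejected(self):
        with pytest.raises(DomainError):
            monthly_climatology(daily_series(np.zeros((0, 2, 2))))


class TestExtremes:
    def test_flat_layers(self):
        t_min, t_max, rng = extremes_and_range(make_grid(np.full((12, 1, 1), 10.0)))
        assert (t_min[0, 0], t_max[0, 0], rng[0, 0]) == (10.0, 10.0, 0.0)

    def test_monthly_ramp(self):
        vals = np.arange(1, 13, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        t_min, t_max, rng = extremes_and_range(make_grid(vals))
        assert np.allclose(t_min, 1.0) and np.allclose(t_max, 12.0) and np.allclose(rng, 11.0)

    def test_sinusoidal_cycle_matches_sampled_extremes(self):
        m = np.arange(12)
        curve = 15.0 + 8.0 * np.sin(2 * np.pi * m / 12.0)
        vals = curve[:, None, None] * np.ones((1, 1, 1))
        _, _, rng = extremes_and_range(make_grid(vals))
        assert rng[0, 0] == pytest.approx(curve.max() - curve.min())

    def test_masked_cell_propagates(self):
        vals = np.full((12, 1, 2), 5.0)
        vals[:, 0, 1] = np.nan
        t_min, _, rng = extremes_and_range(make_grid(vals))
        assert np.isnan(t_min[0, 1]) and np.isnan(rng[0, 1])
        frame = extremes_frame(make_grid(vals))
        assert len(frame) == 1


class TestCoarsen:
    def test_constant_field(self):
        fine = make_grid(np.full((12, 10, 10), 3.3),
                         lat=np.arange(10) * 0.05, lon=np.arange(10) * 0.05)
        coarse = coarsen(fine, 10)
        assert coarse.monthly_mean.shape == (12, 1, 1)
        assert np.allclose(coarse.monthly_mean, 3.3)

    def test_mask_aware_mean(self):
        vals = np.full((12, 10, 10), 7.0)
        vals[:, :, :5] = np.nan  # half the block masked; the rest all 7
        fine = make_grid(vals, lat=np.arange(10) * 0.05, lon=np.arange(10) * 0.05)
        coarse = coarsen(fine, 10)
        assert coarse.monthly_mean[0, 0, 0] == pytest.approx(7.0)

    def test_fully_masked_block_stays_masked(self):
        vals = np.full((12, 10, 20), 7.0)
        vals[:, :, 10:] = np.nan
        fine = make_grid(vals, lat=np.arange(10) * 0.05, lon=np.arange(20) * 0.05)
        coarse = coarsen(fine, 10)
        assert coarse.valid_mask[0, 0] and not coarse.valid_mask[0, 1]

    def test_equatorial_checkerboard_averages_to_one(self):
        ii, jj = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        board = ((ii + jj) % 2) * 2.0  # alternating 0 / 2
        vals = board[None] * np.ones((12, 1, 1))
        fine = make_grid(vals, lat=np.arange(10) * 0.05, lon=np.arange(10) * 0.05)
        coarse = coarsen(fine, 10)
        assert coarse.monthly_mean[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_range_of_constant_field_is_zero_after_coarsening(self):
        fine = make_grid(np.full((12, 10, 10), 9.1),
                         lat=np.arange(10) * 0.05, lon=np.arange(10) * 0.05)
        _, _, rng = extremes_and_range(coarsen(fine, 10))
        assert np.allclose(rng, 0.0)

    def test_indivisible_dims_rejected(self):
        fine = make_grid(np.zeros((12, 9, 10)),
                         lat=np.arange(9) * 0.05, lon=np.arange(10) * 0.05)
        with pytest.raises(GeometryError):
            coarsen(fine, 10)


class TestDepthMask:
    def test_band_membership(self):
        bathy = xr.DataArray([[5.0, 200.0, 10.0, 0.0, -3.0]], dims=("lat", "lon"))
        mask = depth_mask(bathy)
        assert mask.tolist() == [[True, False, True, False, False]]


class TestTPS:
    def test_constant_nodes(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 3.0]])
        out = tps_interpolate(nodes, np.full(4, 4.2), np.array([[0.5, 0.5], [5.0, -2.0]]))
        assert np.allclose(out, 4.2, atol=1e-10)

    def test_node_exactness(self):
        rng = np.random.default_rng(0)
        nodes = rng.uniform(0, 10, size=(15, 2))
        vals = rng.normal(size=15)
        out = tps_interpolate(nodes, vals, nodes)
        assert np.allclose(out, vals, atol=1e-8)

    def test_affine_reproduction(self):
        rng = np.random.default_rng(1)
        nodes = rng.uniform(0, 10, size=(12, 2))
        vals = 2 * nodes[:, 0] + 3 * nodes[:, 1] + 1
        targets = rng.uniform(0, 10, size=(40, 2))
        out = tps_interpolate(nodes, vals, targets)
        assert np.allclose(out, 2 * targets[:, 0] + 3 * targets[:, 1] + 1, atol=1e-8)

    def test_too_few_or_collinear_nodes(self):
        with pytest.raises(DegenerateDesignError):
            tps_interpolate(np.array([[0.0, 0], [1, 1]]), np.array([1.0, 2.0]),
                            np.array([[0.5, 0.5]]))
        collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateDesignError):
            tps_interpolate(collinear, np.arange(4.0), np.array([[0.5, 0.5]]))


class TestDeltaDownscale:
    @pytest.fixture()
    def baseline(self):
        rng = np.random.default_rng(5)
        vals = 15 + rng.normal(0, 2, size=(12, 8, 8))
        vals[:, 0, 0] = np.nan  # one masked cell
        return make_grid(vals)

    @pytest.fixture()
    def coarse_pair(self, baseline):
        lat = np.linspace(baseline.lat[0], baseline.lat[-1], 4)
        lon = np.linspace(baseline.lon[0], baseline.lon[-1], 4)
        hist = ClimGrid(lat, lon, np.full((12, 4, 4), 10.0))
        return hist, lat, lon

    def test_zero_delta_is_identity(self, baseline, coarse_pair):
        hist, lat, lon = coarse_pair
        fut = ClimGrid(lat, lon, hist.monthly_mean.copy())
        out = delta_downscale(hist, fut, baseline)
        valid = baseline.valid_mask
        assert np.allclose(
            out.monthly_mean[:, valid], baseline.monthly_mean[:, valid], atol=1e-12
        )
        assert (out.valid_mask == baseline.valid_mask).all()

    def test_constant_delta(self, baseline, coarse_pair):
        hist, lat, lon = coarse_pair
        fut = ClimGrid(lat, lon, hist.monthly_mean + 2.0)
        out = delta_downscale(hist, fut, baseline)
        valid = baseline.valid_mask
        assert np.allclose(
            out.monthly_mean[:, valid] - baseline.monthly_mean[:, valid], 2.0, atol=1e-9
        )

    def test_affine_delta_reproduced_at_fine_centers(self, baseline, coarse_pair):
        hist, lat, lon = coarse_pair
        lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
        delta = 0.05 * lat2d + 0.01 * lon2d
        fut = ClimGrid(lat, lon, hist.monthly_mean + delta[None])
        out = delta_downscale(hist, fut, baseline)
        blat, blon = np.meshgrid(baseline.lat, baseline.lon, indexing="ij")
        expected = 0.05 * blat + 0.01 * blon
        valid = baseline.valid_mask
        got = out.monthly_mean[0] - baseline.monthly_mean[0]
        assert np.allclose(got[valid], expected[valid], atol=1e-6)

    def test_masks_are_monotone(self, baseline, coarse_pair):
        hist, lat, lon = coarse_pair
        fut = ClimGrid(lat, lon, hist.monthly_mean + 1.0)
        out = delta_downscale(hist, fut, baseline)
        assert not out.valid_mask[0, 0]  # masked baseline cell stays masked

    def test_geometry_mismatch_rejected(self, baseline, coarse_pair):
        hist, lat, lon = coarse_pair
        other = ClimGrid(lat + 1.0, lon, hist.monthly_mean.copy())
        with pytest.raises(GeometryError):
            delta_downscale(hist, other, baseline)


class TestEnsembleMean:
    def test_single_member_identity(self):
        g = make_grid(np.random.default_rng(0).normal(size=(12, 3, 3)))
        out = ensemble_mean([g])
        assert np.allclose(out.monthly_mean, g.monthly_mean)

    def test_pairwise_mean(self):
        a = make_grid(np.full((12, 2, 2), 4.0))
        b = make_grid(np.full((12, 2, 2), 6.0))
        assert np.allclose(ensemble_mean([a, b]).monthly_mean, 5.0)

    def test_three_members_match_direct_mean(self):
        rng = np.random.default_rng(9)
        vals = [rng.normal(size=(12, 2, 2)) for _ in range(3)]
        grids = [make_grid(v) for v in vals]
        assert np.allclose(
            ensemble_mean(grids).monthly_mean, np.mean(vals, axis=0)
        )

    def test_geometry_mismatch(self):
        a = make_grid(np.zeros((12, 2, 2)))
        b = make_grid(np.zeros((12, 3, 3)))
        with pytest.raises(GeometryError):
            ensemble_mean([a, b])


class TestNetcdfRoundtrip:
    def test_climgrid_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        vals = rng.normal(15, 3, size=(12, 4, 5))
        vals[:, 1, 2] = np.nan
        grid = make_grid(vals, lat=np.arange(4) * 0.5 + 30.25,
                         lon=np.arange(5) * 0.5 - 75.75)
        path = tmp_path / "clim.nc"
        grid.to_netcdf(path)
        back = ClimGrid.from_netcdf(path)
        assert np.allclose(back.lat, grid.lat) and np.allclose(back.lon, grid.lon)
        valid = grid.valid_mask
        assert (back.valid_mask == valid).all()
        assert np.allclose(back.monthly_mean[:, valid], grid.monthly_mean[:, valid], atol=1e-9)


def test_haversine_known_distance():
    # one degree of latitude is ~111.2 km on a 6371 km sphere
    assert float(haversine_km(40.0, -70.0, 41.0, -70.0)) == pytest.approx(111.19, abs=0.05)
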