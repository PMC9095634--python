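"""Flux-divergence deposition, loss frequency, lifetime, seasonal means."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import dustflux as dfx
from dustflux.grids import GridDef


def column_field(grid, col_u, col_v):
    lats, lons = grid.lat_centers, grid.lon_centers
    return xr.Dataset(
        {
            "column_flux_u": (("lat", "lon"), np.broadcast_to(col_u, (lats.size, lons.size)).astype(float)),
            "column_flux_v": (("lat", "lon"), np.broadcast_to(col_v, (lats.size, lons.size)).astype(float)),
        },
        coords={"lat": lats, "lon": lons},
    )


class TestDivergenceDeposition:
    def test_oracle_recovery_within_2pct(self, gaussian_scenario):
        sc = gaussian_scenario
        est = dfx.divergence_deposition(dfx.scenario_flux_field(sc), grid=sc.grid)
        truth = sc.truth_deposition.sum()
        got = est.attrs["total_deposition_g_s"]
        assert abs(got - truth) / truth < 0.02

    def test_convergence_under_refinement(self):
        errs = []
        for cell in (2.0, 1.0, 0.5):
            grid = GridDef(cell_deg=cell)
            sc = dfx.make_plume("gaussian_plume", grid=grid)
            est = dfx.divergence_deposition(dfx.scenario_flux_field(sc), grid=grid)
            truth = sc.truth_deposition.sum()
            errs.append(abs(est.attrs["total_deposition_g_s"] - truth) / truth)
        assert errs[0] > errs[1] > errs[2]

    def test_divergence_free_field_deposits_nothing(self, small_grid):
        # uniform zonal density; meridional density ~ 1/cos(lat) keeps the
        # flux through shrinking east-west faces constant on the sphere
        ff = column_field(small_grid, 0.5, 0.0)
        est = dfx.divergence_deposition(ff, grid=small_grid)
        np.testing.assert_allclose(est["raw_divergence"].values, 0.0, atol=1e-9)
        assert est.attrs["total_deposition_g_s"] == pytest.approx(0.0, abs=1e-9)
        assert not est["negative_flag"].values.any()
        # meridional density ~ 1/cos(lat) keeps the flux through shrinking
        # east-west faces constant; centred faces leave only O(dlat^2) residual
        col_v = -0.2 / np.cos(np.deg2rad(small_grid.lat_centers))
        ff["column_flux_v"] = (
            ("lat", "lon"),
            np.broadcast_to(col_v[:, None], ff["column_flux_v"].shape).copy(),
        )
        est2 = dfx.divergence_deposition(ff, grid=small_grid)
        scale = 0.2 * small_grid.zonal_face_length(15.0)
        interior = est2["raw_divergence"].values[1:-1, :]  # edges are one-sided
        assert np.abs(interior).max() < 1e-3 * scale

    def test_step_down_concentrates_deposition(self):
        """3-cell row, flux stepping down along the wind: hand calculation."""
        grid = GridDef(lat_min=10, lat_max=14, lon_min=50, lon_max=56, cell_deg=2)
        ff = column_field(grid, 0.0, 0.0)
        ff["column_flux_u"][:, :] = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
        est = dfx.divergence_deposition(ff, grid=grid)
        L = grid.meridional_face_length()
        # faces (one-sided edges): [1, 1, 0.5, 0] -> cells get [0, 0.5L, 0.5L]
        expected = np.array([[0.0, 0.5 * L, 0.5 * L], [0.0, 0.5 * L, 0.5 * L]])
        np.testing.assert_allclose(est["ddf"].values, expected, rtol=1e-12)

    def test_mass_budget_totals_match_boundary(self, gaussian_scenario):
        """Signed total equals boundary inflow - outflow exactly."""
        sc = gaussian_scenario
        est = dfx.divergence_deposition(dfx.scenario_flux_field(sc), grid=sc.grid)
        net = est.attrs["boundary_inflow_g_s"] - est.attrs["boundary_outflow_g_s"]
        assert est.attrs["total_signed_divergence_g_s"] == pytest.approx(net, rel=1e-12)

    def test_negative_cells_flagged_and_excluded(self):
        grid = GridDef(lat_min=10, lat_max=14, lon_min=50, lon_max=56, cell_deg=2)
        ff = column_field(grid, 0.0, 0.0)
        ff["column_flux_u"][:, :] = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        est = dfx.divergence_deposition(ff, grid=grid)
        assert est["negative_flag"].values[:, 0].all()  # flux grows downwind
        assert np.all(est["ddf"].values >= 0)
        signed = est.attrs["total_signed_divergence_g_s"]
        clipped = est.attrs["total_deposition_g_s"]
        assert clipped > signed

    def test_single_cell_grid_rejected(self):
        grid = GridDef(lat_min=10, lat_max=12, lon_min=50, lon_max=52, cell_deg=2)
        with pytest.raises(ValueError, match="single-cell"):
            dfx.divergence_deposition(column_field(grid, 1.0, 0.0), grid=grid)

    def test_ocean_mask_blanks_land(self, small_grid):
        mask = np.ones((5, 5), dtype=bool)
        mask[0, 0] = False
        sc = dfx.make_plume("gaussian_plume", grid=small_grid)
        est = dfx.divergence_deposition(
            dfx.scenario_flux_field(sc), grid=small_grid, ocean_mask=mask
        )
        assert np.isnan(est["ddf"].values[0, 0])


class TestLossFrequencyLifetime:
    def test_ratio_and_inverse(self):
        assert dfx.loss_frequency(0.5, 1.0) == pytest.approx(0.5)
        assert dfx.lifetime(0.5) == pytest.approx(2.0)
        assert dfx.lifetime(2.5) == pytest.approx(0.4)  # short JJA-like lifetime

    def test_zero_and_missing(self):
        assert dfx.loss_frequency(0.0, 1.0) == 0.0
        assert np.isnan(dfx.lifetime(0.0))
        assert np.isnan(dfx.lifetime(np.nan))
        assert np.isnan(dfx.loss_frequency(0.5, 0.0))

    def test_dlf_invariant_to_dmee(self, small_grid):
        """DMEE cancels in DLF; DDF itself scales as 1/DMEE."""
        sc = dfx.make_plume("gaussian_plume", grid=small_grid)
        dls = {}
        dext = sc.concentration * 0.37 * 1000.0  # fixed extinction field, km^-1
        for dmee in (0.37, 0.5):
            dg = xr.Dataset(
                {"dext": (("lat", "lon", "alt_bin"), dext)},
                coords={
                    "lat": small_grid.lat_centers,
                    "lon": small_grid.lon_centers,
                    "alt_bin": small_grid.alt_mids,
                },
                attrs={"dext_units": "km-1"},
            )
            winds = dfx.make_winds(small_grid)
            winds["u"] = (("lat", "lon", "alt_bin"), sc.winds_u)
            winds["v"] = (("lat", "lon", "alt_bin"), sc.winds_v)
            ff = dfx.flux_profiles(dg, winds, dfx.FluxParams(dmee=dmee))
            est = dfx.divergence_deposition(ff, grid=small_grid)
            dlf = dfx.loss_frequency(est["ddf_area"].values, ff["loading"].values)
            dls[dmee] = dlf
        np.testing.assert_allclose(dls[0.37], dls[0.5], rtol=1e-10, equal_nan=True)

    def test_dlt_times_dlf_is_one(self, rng):
        dlf = rng.uniform(0.1, 5.0, size=50)
        np.testing.assert_allclose(dfx.lifetime(dlf) * dlf, 1.0, rtol=1e-12)


class TestSeasonalAggregate:
    @staticmethod
    def monthly_stack(values_by_month):
        times = pd.to_datetime(
            [f"{yr}-{m:02d}" for yr in (2007, 2008) for m in range(1, 13)]
        )
        data = np.array(
            [values_by_month[t.month] for t in times], dtype=float
        )[:, None, None] * np.ones((1, 2, 2))
        return xr.DataArray(
            data,
            dims=("time", "lat", "lon"),
            coords={"time": times, "lat": [10, 12], "lon": [50, 52]},
        )

    def test_identical_months_zero_sd(self):
        stack = self.monthly_stack({m: 3.0 for m in range(1, 13)})
        mean, sd, cov = dfx.seasonal_aggregate(stack, "JJA")
        assert float(mean.isel(lat=0, lon=0)) == 3.0
        assert float(sd.isel(lat=0, lon=0)) == 0.0
        assert cov == 1.0

    def test_known_seasonal_cycle_recovered(self):
        cycle = {m: float(m) for m in range(1, 13)}
        stack = self.monthly_stack(cycle)
        mean, _, _ = dfx.seasonal_aggregate(stack, "JJA")
        assert float(mean.isel(lat=0, lon=0)) == pytest.approx(7.0)  # (6+7+8)/3
        mean_son, _, _ = dfx.seasonal_aggregate(stack, "SON")
        assert float(mean_son.isel(lat=0, lon=0)) == pytest.approx(10.0)

    def test_missing_month_coverage_reported(self):
        stack = self.monthly_stack({m: 1.0 for m in range(1, 13)})
        partial = stack.sel(time=stack["time"].dt.month != 6)
        mean, _, cov = dfx.seasonal_aggregate(partial, "JJA")
        assert float(mean.isel(lat=0, lon=0)) == 1.0
        assert cov == pytest.approx(4 / 6)

    def test_unknown_season_rejected(self):
        stack = self.monthly_stack({m: 1.0 for m in range(1, 13)})
        with pytest.raises(ValueError, match="season"):
            dfx.seasonal_aggregate(stack, "XYZ")
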