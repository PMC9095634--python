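"""Screening, depolarization partitioning, extinction, DOD, gridding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

import dustflux as dfx
from dustflux.retrieval import profile_dod_binned

PARAMS = dfx.RetrievalParams()


class TestScreening:
    def test_inside_window_retained(self):
        g = dfx.make_granule(dfx.GranuleSpec(n_profiles=5, cad_outlier_fraction=0.0))
        screened, rep = dfx.screen(g)
        assert rep["profiles_retained"] == 5
        assert rep["levels_removed"] == 0

    def test_outliers_removed_bookkeeping(self):
        g = dfx.make_granule(
            dfx.GranuleSpec(n_profiles=100, cad_outlier_fraction=0.2, seed=3)
        )
        screened, rep = dfx.screen(g)
        assert rep["profiles_retained"] == 80
        assert rep["profiles_removed"] == 20

    def test_all_removed_yields_empty_not_error(self):
        g = dfx.make_granule(
            dfx.GranuleSpec(n_profiles=4, cad_outlier_fraction=1.0, seed=2)
        )
        screened, rep = dfx.screen(g)
        assert screened.sizes["profile"] == 0
        assert rep["profiles_retained"] == 0


class TestDustFraction:
    @pytest.mark.parametrize(
        "pdr,expected",
        [
            (0.25, 1.0),  # dust endmember
            (0.045, 0.0),  # non-dust endmember
            (0.14, 0.5081),  # mid-mixture, frozen from the closed form
            (0.5, 1.0),  # beyond dust endmember clips to 1
            (0.0, 0.0),  # below non-dust endmember clips to 0
        ],
    )
    def test_values(self, pdr, expected):
        assert dfx.dust_fraction(pdr, PARAMS) == pytest.approx(expected, abs=1e-4)

    def test_brute_force_mixture_inversion(self):
        """f_d(mixed PDR) equals the dust share found by searching mixtures."""
        d_d, d_nd = PARAMS.delta_dust, PARAMS.delta_nondust
        weights = np.linspace(0, 1, 2001)
        pdr_target = 0.14
        mixed = dfx.mix_pdr(weights, 1 - weights, d_d, d_nd)
        w_star = weights[np.argmin(np.abs(mixed - pdr_target))]
        assert dfx.dust_fraction(pdr_target, PARAMS) == pytest.approx(w_star, abs=1e-3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            dfx.RetrievalParams(delta_dust=0.045, delta_nondust=0.25)

    @given(
        pdr=st.lists(st.floats(0, 0.8), min_size=2, max_size=20),
        d_nd=st.floats(0.0, 0.1),
        gap=st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_pdr(self, pdr, d_nd, gap):
        p = dfx.RetrievalParams(delta_dust=d_nd + gap, delta_nondust=d_nd)
        x = np.sort(np.asarray(pdr))
        f = dfx.dust_fraction(x, p)
        assert np.all(np.diff(f) >= -1e-12)

    @given(
        w=st.floats(0.0, 1.0),
        d_nd=st.floats(0.0, 0.1),
        gap=st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_mix_round_trip(self, w, d_nd, gap):
        """Exact round trip for any endmember pair with delta_d > delta_nd."""
        d_d = d_nd + gap
        pdr = dfx.mix_pdr(w, 1 - w, d_d, d_nd)
        p = dfx.RetrievalParams(delta_dust=d_d, delta_nondust=d_nd)
        assert dfx.dust_fraction(pdr, p) == pytest.approx(w, abs=1e-9)


class TestDustExtinction:
    def test_arithmetic(self):
        assert dfx.dust_extinction(0.001, 44.0) == pytest.approx(0.044)
        assert dfx.dust_extinction(0.0, 44.0) == 0.0
        assert dfx.dust_extinction(0.001, 44.0, to_Mm=True) == pytest.approx(44.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dfx.dust_extinction(-0.1, 44.0)

    def test_round_trip_zero_noise(self, clean_granule):
        """Retrieved dust extinction matches the generator's truth."""
        part = dfx.partition_granule(clean_granule)
        truth = clean_granule["dust_extinction_true"].values
        got = part["dust_extinction"].values
        nz = truth > 0
        rel = np.abs(got[:, nz] - truth[None, nz]) / truth[None, nz]
        assert rel.max() < 1e-10


class TestColumnDOD:
    def test_uniform_layer(self):
        alt = np.linspace(0.0, 2000.0, 41)
        dod = dfx.column_dod(np.full(alt.size, 0.1), alt)
        assert dod == pytest.approx(0.2, rel=1e-12)

    def test_all_missing_gives_nan(self):
        alt = np.arange(0.0, 2001.0, 60.0)
        assert np.isnan(dfx.column_dod(np.full(alt.size, np.nan), alt))

    def test_gaussian_layer_matches_erf_integral(self):
        alt = np.arange(0.0, 7001.0, 60.0)
        a0, z0, sig = 0.2, 3000.0, 500.0
        prof = a0 * np.exp(-((alt - z0) ** 2) / (2 * sig**2))
        sig_km, z0_km = sig / 1000, z0 / 1000
        analytic = (
            a0
            * sig_km
            * np.sqrt(np.pi / 2)
            * (erf((7.0 - z0_km) / (np.sqrt(2) * sig_km)) - erf((0 - z0_km) / (np.sqrt(2) * sig_km)))
        )
        assert dfx.column_dod(prof, alt) == pytest.approx(analytic, rel=5e-3)

    def test_ceiling_excludes_levels_above(self):
        alt = np.array([0.0, 3500.0, 8000.0])
        dod = dfx.column_dod(np.array([0.1, 0.1, 10.0]), alt, z_top=7000.0)
        assert dod == pytest.approx(0.1 * 3.5)


class TestGridding:
    def test_two_identical_profiles_mean_idempotent(self, small_grid):
        g = dfx.make_granule(
            dfx.GranuleSpec(n_profiles=2, lat_range=(14.9, 15.1), lon_range=(54.9, 55.1), seed=1)
        )
        grid_ds = dfx.grid_monthly(g, small_grid)
        cell = grid_ds.sel(lat=15, lon=55)
        assert int(cell["n_samples"]) == 2
        part = dfx.partition_granule(g)
        # both profiles identical (zero noise) so the mean equals either
        one = part["dust_extinction"].values[0]
        in_bin = (g["level"].values >= 0) & (g["level"].values < 1000)
        assert cell["dext"].values[0] == pytest.approx(one[in_bin].mean())

    def test_profiles_outside_grid_dropped(self, small_grid):
        g = dfx.make_granule(
            dfx.GranuleSpec(n_profiles=10, lat_range=(30, 35), lon_range=(54, 56), seed=4)
        )
        grid_ds = dfx.grid_monthly(g, small_grid)
        assert grid_ds.attrs["profiles_dropped_outside_grid"] == 10
        assert int(grid_ds["n_samples"].sum()) == 0
        assert np.isnan(grid_ds["dext"].values).all()

    def test_grid_dod_is_mean_of_profile_dods(self, small_grid, clean_granule):
        """Cell DOD equals the mean of binned per-profile DODs (linearity)."""
        part = dfx.partition_granule(clean_granule)
        grid_ds = dfx.grid_monthly(part, small_grid)
        prof_dod = profile_dod_binned(part, small_grid)
        ilat, ilon = small_grid.cell_index(
            part["lat"].values, part["lon"].values
        )
        for r in np.unique(ilat):
            for c in np.unique(ilon[ilat == r]):
                sel = (ilat == r) & (ilon == c)
                assert grid_ds["dod"].values[r, c] == pytest.approx(
                    prof_dod[sel].mean(), rel=1e-12
                )

    def test_noisy_cell_mean_within_three_se(self, small_grid):
        """200 noisy profiles per cell: mean within 3 SE of the truth."""
        spec = dfx.GranuleSpec(
            n_profiles=200,
            lat_range=(14.5, 15.5),
            lon_range=(54.5, 55.5),
            dust_layers=((1000.0, 3000.0, 0.1),),
            nondust_background=0.01,
            noise_sd_rel=0.1,
            seed=21,
        )
        g = dfx.make_granule(spec)
        part = dfx.partition_granule(g)
        grid_ds = dfx.grid_monthly(part, small_grid)
        # truth in the 1-2 km bin: pure in-layer dust extinction
        cell = grid_ds.sel(lat=15, lon=55)
        got = float(cell["dext"].values[1])
        lvl = g["level"].values
        in_bin = (lvl >= 1000) & (lvl < 2000)
        samples = part["dust_extinction"].values[:, in_bin]
        se = samples.mean(axis=1).std(ddof=1) / np.sqrt(spec.n_profiles)
        truth = 0.1
        assert abs(got - truth) < 3 * se + 1e-12
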