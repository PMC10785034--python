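import numpy as np
import pytest

from aqhia import synth
from aqhia.grids import GridSpec


def config(**kw):
    base = dict(met_year="2020", scenario="BAU", seed=0)
    base.update(kw)
    return synth.ScenarioConfig(**base)


class TestScenarioFields:
    def test_degenerate_deterministic_case(self, small_grid):
        c = config(
            o3_background=40.0,
            o3_enhancement=10.0,
            enhancement_pattern="uniform",
            diurnal_amplitude=0.0,
            seasonal_amplitude=0.0,
            noise_sd=0.0,
        )
        f = synth.generate_scenario_fields(small_grid, [c], n_days=3)
        np.testing.assert_array_equal(f[("2020", "BAU")]["o3"].values, 50.0)

    def test_bit_identical_reproducibility(self, small_grid):
        cs = [config(), config(scenario="COV", monthly_reduction=tuple([0.1] * 12))]
        a = synth.generate_scenario_fields(small_grid, cs, n_days=4)
        b = synth.generate_scenario_fields(small_grid, cs, n_days=4)
        for key in a:
            for var in ("o3", "pm25"):
                np.testing.assert_array_equal(a[key][var].values, b[key][var].values)

    def test_ar1_noise_mean_within_clt_bound(self):
        # oracle: variance of the mean of a stationary AR(1) with marginal SD s
        # is approximately s^2 (1+rho) / (n (1-rho))
        grid = GridSpec(n_lat=1, n_lon=1)
        rho, sd, n = 0.6, 5.0, 8760
        noisy = config(ar1_rho=rho, noise_sd=sd)
        quiet = config(ar1_rho=rho, noise_sd=0.0)
        f_noisy = synth.generate_scenario_fields(grid, [noisy], n_days=365)[("2020", "BAU")]["o3"]
        f_quiet = synth.generate_scenario_fields(grid, [quiet], n_days=365)[("2020", "BAU")]["o3"]
        resid = f_noisy.values - f_quiet.values
        se = sd / np.sqrt(n * (1 - rho) / (1 + rho))
        assert abs(resid.mean()) < 4 * se

    @pytest.mark.parametrize("pattern", ["uniform", "urban"])
    def test_scenario_separability_zero_noise(self, small_grid, pattern):
        red = tuple(np.linspace(0.05, 0.3, 12))
        bau = config(noise_sd=0.0, enhancement_pattern=pattern)
        cov = config(scenario="COV", noise_sd=0.0, enhancement_pattern=pattern, monthly_reduction=red)
        f = synth.generate_scenario_fields(small_grid, [bau, cov], n_days=40)
        o3b = f[("2020", "BAU")]["o3"]
        o3c = f[("2020", "COV")]["o3"]
        enh = synth.enhancement_field(small_grid, bau)
        months = o3b["time"].dt.month.values
        expected = o3b.values - enh[None] * np.asarray(red)[months - 1][:, None, None]
        np.testing.assert_allclose(o3c.values, expected, rtol=1e-12, atol=1e-12)

    def test_missing_bau_partner_rejected(self, small_grid):
        cov = config(scenario="COV", monthly_reduction=tuple([0.1] * 12))
        with pytest.raises(ValueError, match="BAU partner"):
            synth.generate_scenario_fields(small_grid, [cov], n_days=2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            config(diurnal_amplitude=-1.0)
        with pytest.raises(ValueError, match="BAU"):
            config(monthly_reduction=tuple([0.1] * 12))
        with pytest.raises(ValueError, match="rho"):
            config(ar1_rho=1.0)

    def test_fields_non_negative(self, small_grid):
        c = config(noise_sd=25.0, o3_background=5.0)
        f = synth.generate_scenario_fields(small_grid, [c], n_days=10)
        assert f[("2020", "BAU")]["o3"].values.min() >= 0.0
        assert f[("2020", "BAU")]["pm25"].values.min() >= 0.0


class TestPopulation:
    def test_uniform_limit(self, small_grid):
        pop = synth.generate_population(small_grid, n_centers=1, decay=0.0, dispersion=0.0, total=1000.0)
        np.testing.assert_allclose(pop.values, 1000.0 / 20)

    def test_total_is_exact(self, small_grid):
        pop = synth.generate_population(small_grid, n_centers=5, seed=3, total=2.5e6)
        assert pop.values.sum() == pytest.approx(2.5e6, rel=1e-12)
        assert (pop.values >= 0).all()

    def test_deterministic_under_seed(self, small_grid):
        a = synth.generate_population(small_grid, seed=11)
        b = synth.generate_population(small_grid, seed=11)
        np.testing.assert_array_equal(a.values, b.values)


class TestMortality:
    def test_zero_sd_gives_constant_rate(self, small_grid):
        m = synth.generate_mortality(small_grid, n_counties=4, mean_rate=0.009, sd_rate=0.0)
        np.testing.assert_array_equal(m["rate"].values, 0.009)

    def test_single_county(self, small_grid):
        m = synth.generate_mortality(small_grid, n_counties=1, mean_rate=0.01, sd_rate=0.001)
        assert len(np.unique(m["county_id"].values)) == 1

    def test_rate_constant_within_county(self, small_grid):
        m = synth.generate_mortality(small_grid, n_counties=4, mean_rate=0.01, sd_rate=0.002, seed=5)
        for cid in np.unique(m["county_id"].values):
            rates = m["rate"].values[m["county_id"].values == cid]
            assert len(np.unique(rates)) == 1

    def test_county_mean_within_clt_bound(self):
        grid = GridSpec(n_lat=20, n_lon=20)
        mean_rate, sd_rate, n = 0.009, 0.002, 100
        m = synth.generate_mortality(grid, n_counties=n, mean_rate=mean_rate, sd_rate=sd_rate, seed=2)
        county_rates = [
            m["rate"].values[m["county_id"].values == cid][0] for cid in np.unique(m["county_id"].values)
        ]
        assert abs(np.mean(county_rates) - mean_rate) < 4 * sd_rate / np.sqrt(n)
        assert all(0 < r < 1 for r in county_rates)


class TestActivity:
    def test_zero_depth_is_reference_series(self):
        prof = {"s": synth.CovidSectorProfile(0.0, 4, 0.3)}
        act = synth.generate_activity(["s"], covid_profile=prof)
        np.testing.assert_array_equal(act["scaling"].values, 1.0)

    def test_april_gasoline_trough(self):
        act = synth.generate_activity(["onroad_gasoline"])
        april = act.query("month == 4")["scaling"].iloc[0]
        assert april == pytest.approx(0.6)

    def test_zero_rebound_stays_at_trough(self):
        prof = {"s": synth.CovidSectorProfile(0.3, 4, 0.0)}
        act = synth.generate_activity(["s"], covid_profile=prof)
        after = act.query("month >= 4")["scaling"].values
        np.testing.assert_allclose(after, 0.7)
        np.testing.assert_array_equal(act.query("month < 4")["scaling"].values, 1.0)

    def test_depth_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            synth.CovidSectorProfile(1.4, 4, 0.3)


class TestSatelliteScene:
    def test_self_consistency_noise_free_model_apriori(self, small_grid):
        col = small_grid.surface(np.full(small_grid.shape, 3e15))
        pixels = synth.generate_satellite_scene(col, small_grid, n_pixels=20, noise=0.0, apriori="model")
        for p in pixels:
            assert p.vcd == pytest.approx(3e15, rel=1e-12)

    def test_flat_scattering_weights_give_unit_amf(self, small_grid):
        col = small_grid.surface(np.full(small_grid.shape, 1e15))
        pixels = synth.generate_satellite_scene(
            col, small_grid, n_pixels=10, noise=0.0, sw_surface=1.0, sw_top=1.0, sw_jitter=0.0
        )
        for p in pixels:
            assert p.amf_orig == pytest.approx(1.0, rel=1e-12)

    def test_amf_self_consistent_with_apriori(self, small_grid):
        col = small_grid.surface(np.full(small_grid.shape, 2e15))
        pixels = synth.generate_satellite_scene(col, small_grid, n_pixels=30, seed=4)
        for p in pixels:
            trop = slice(0, p.tropopause_layer + 1)
            expect = np.dot(p.scattering_weights[trop], p.apriori[trop]) / p.apriori[trop].sum()
            assert p.amf_orig == pytest.approx(expect, rel=1e-12)

    def test_mean_relative_column_error_clt(self, small_grid):
        noise = 0.1
        col = small_grid.surface(np.full(small_grid.shape, 5e15))
        pixels = synth.generate_satellite_scene(col, small_grid, n_pixels=10_000, noise=noise, seed=9)
        rel_err = np.array([p.vcd / 5e15 - 1.0 for p in pixels])
        assert abs(rel_err.mean()) < 4 * noise / np.sqrt(10_000)

    def test_deterministic_under_seed(self, small_grid):
        col = small_grid.surface(np.full(small_grid.shape, 1e15))
        a = synth.generate_satellite_scene(col, small_grid, n_pixels=5, seed=3)
        b = synth.generate_satellite_scene(col, small_grid, n_pixels=5, seed=3)
        for pa, pb in zip(a, b):
            assert pa.vcd == pb.vcd and pa.qa == pb.qa
            np.testing.assert_array_equal(pa.scattering_weights, pb.scattering_weights)


class TestColumnFields:
    def test_paired_scenarios_share_meteorological_noise(self, small_grid):
        red = tuple([0.2] * 12)
        bau = config()
        cov = config(scenario="COV", monthly_reduction=red)
        cb = synth.generate_column_fields(small_grid, bau, n_overpasses=10)
        cc = synth.generate_column_fields(small_grid, cov, n_overpasses=10)
        # NO2 ratio COV/BAU is the deterministic emission factor (noise cancels)
        ratio = cc["NO2_col"].values / cb["NO2_col"].values
        assert ratio.std() < 0.2 and (ratio <= 1.0 + 1e-9).all()

    def test_fnr_rises_under_reduction(self, small_grid):
        red = tuple([0.3] * 12)
        bau = config()
        cov = config(scenario="COV", monthly_reduction=red)
        cb = synth.generate_column_fields(small_grid, bau, n_overpasses=30)
        cc = synth.generate_column_fields(small_grid, cov, n_overpasses=30)
        fnr_b = cb["HCHO_col"].mean("time") / cb["NO2_col"].mean("time")
        fnr_c = cc["HCHO_col"].mean("time") / cc["NO2_col"].mean("time")
        assert (fnr_c.values > fnr_b.values).mean() > 0.95


class TestSectorFractions:
    def test_fractions_valid_and_all_regions_present(self):
        grid = GridSpec(n_lat=40, n_lon=60)
        ds = synth.generate_sector_nox_fractions(grid, seed=0)
        total = sum(ds[k].values for k in ("mobile", "point", "og"))
        assert total.max() <= 1.0 + 1e-9 and total.min() >= 0.0
        assert all((ds[k].values >= 0.6).any() for k in ("mobile", "point", "og"))
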