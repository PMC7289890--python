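"""Synthetic site emulation: meteorology, true fluxes, degradation, 10 Hz blocks."""

import numpy as np
import pandas as pd
import pytest

import caatingaflux as cf
from caatingaflux.fluxes import block_covariance_flux
from caatingaflux.solar import clear_sky_rg
from caatingaflux.synthetic import (DegradationSpec, SiteConfig,
                                    degrade_series,
                                    simulate_high_frequency_block,
                                    simulate_met_year, simulate_true_fluxes,
                                    simulate_year)


class TestSiteConfig:
    def test_invalid_veg_range(self):
        with pytest.raises(ValueError):
            SiteConfig(veg_index_range=(0.5, 0.2))
        with pytest.raises(ValueError):
            SiteConfig(veg_index_range=(0.0, 0.4))

    def test_invalid_rain_and_year(self):
        with pytest.raises(ValueError):
            SiteConfig(annual_rain_target=-10.0)
        with pytest.raises(ValueError):
            SiteConfig(year=0)
        with pytest.raises(ValueError):
            SiteConfig(wet_season=("05-31", "01-01"))


class TestSimulateMetYear:
    def test_record_count(self, default_year):
        series, _ = default_year
        assert len(series) == 365 * 48
        assert len(simulate_met_year(SiteConfig(year=2016, seed=0))) == 366 * 48

    def test_degenerate_amplitudes(self):
        cfg = SiteConfig(seed=0, t_diurnal_amp=0.0, t_seasonal_amp=0.0,
                         t_noise_sd=0.0, rain_day_cooling=0.0,
                         cloud_variability=0.0)
        met = simulate_met_year(cfg)
        assert met["ta"].nunique() == 1
        mid = met.index - pd.Timedelta(minutes=15)
        doy = mid.dayofyear.to_numpy(dtype=float)
        hour = mid.hour.to_numpy() + mid.minute.to_numpy() / 60.0
        expected = clear_sky_rg(cfg.latitude, doy, hour, cfg.transmissivity)
        assert np.allclose(met["rg"].to_numpy(), expected)

    def test_annual_rainfall_near_target(self, default_year):
        series, _ = default_year
        total = series["precip"].sum()
        assert abs(total - 513.0) / 513.0 < 0.15

    def test_veg_index_range_and_timing(self, default_year):
        series, _ = default_year
        veg = series["veg_index"]
        assert veg.min() >= 0.16 - 1e-9 and veg.max() <= 0.42 + 1e-9
        peak = veg.idxmax()
        assert "01-01" <= peak.strftime("%m-%d") <= "05-31"

    def test_radiation_zero_at_night(self, default_year):
        series, _ = default_year
        assert (series["rg"] >= 0).all()
        # deep night: local midnight to 3am must be dark at this longitude
        hours = (series.index - pd.Timedelta(minutes=15)).hour
        assert (series["rg"][(hours >= 0) & (hours < 3)] == 0).all()

    def test_vpd_consistent_with_magnus(self, default_year):
        series, _ = default_year
        from caatingaflux.synthetic import magnus_svp
        es = magnus_svp(series["ta"].to_numpy())
        expected = es * (1.0 - series["rh"].to_numpy() / 100.0)
        assert np.allclose(series["vpd"].to_numpy(), expected, atol=1e-9)
        assert series["rh"].between(0, 100).all()

    def test_reproducible_under_seed(self):
        a = simulate_met_year(SiteConfig(seed=11))
        b = simulate_met_year(SiteConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTrueFluxes:
    def test_identity_noiseless(self, noiseless_year):
        series, truth = noiseless_year
        resid = series["nee"] - (truth.true_reco - truth.true_gpp)
        assert np.abs(resid.to_numpy()).max() == 0.0

    def test_gpp_zero_in_dark(self, default_year):
        series, truth = default_year
        dark = series["rg"] == 0.0
        assert (truth.true_gpp[dark] == 0.0).all()
        assert (truth.true_gpp >= 0.0).all()
        assert (truth.true_reco >= 0.0).all()

    def test_no_light_nee_equals_reco(self):
        cfg = SiteConfig(seed=5, noise_sd_nee=0.0)
        met = simulate_met_year(cfg)
        met["rg"] = 0.0
        truth = simulate_true_fluxes(met, cf.LloydTaylorParams(),
                                     cf.LightResponseParams(-0.05, -20.0, 0.0),
                                     cfg)
        assert np.array_equal(truth.nee_observed.to_numpy(),
                              truth.true_reco.to_numpy())

    def test_gappy_met_rejected(self):
        cfg = SiteConfig(seed=5)
        met = simulate_met_year(cfg)
        met.iloc[10, met.columns.get_loc("ta")] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            simulate_true_fluxes(met, cf.LloydTaylorParams(),
                                 cf.LightResponseParams(-0.05, -20.0, 0.0), cfg)


class TestDegradeSeries:
    def test_all_zero_spec_is_identity(self, default_year):
        series, truth = default_year
        spec = DegradationSpec(gap_fraction=0.0, block_gap_lengths=(),
                               spike_count=0, calm_night_fraction=0.0,
                               suppress_low_ustar=False)
        out, ledger = degrade_series(series, truth, spec)
        pd.testing.assert_frame_equal(out, series)
        assert len(ledger.gap_positions) == 0 and len(ledger.spikes) == 0

    def test_gap_count_and_ledger_complete(self, degraded_year):
        degraded, ledger, _ = degraded_year
        n = len(degraded)
        missing = np.flatnonzero(degraded["nee"].isna().to_numpy())
        assert np.array_equal(np.sort(ledger.gap_positions), missing)
        assert abs(len(missing) - 0.10 * n) <= max(DegradationSpec().block_gap_lengths)

    def test_spikes_match_ledger(self, default_year):
        series, truth = default_year
        spec = DegradationSpec(gap_fraction=0.0, block_gap_lengths=(),
                               spike_count=5, spike_magnitude=10.0,
                               calm_night_fraction=0.0,
                               suppress_low_ustar=False, seed=9)
        out, ledger = degrade_series(series, truth, spec)
        assert len(ledger.spikes) == 5
        nee = series["nee"].to_numpy()
        mad = np.median(np.abs(nee - np.median(nee)))
        for pos, delta in ledger.spikes:
            local = nee[max(0, pos - 24):pos + 25]
            dist = abs(out["nee"].iloc[pos] - np.median(local))
            assert dist >= 10.0 * mad * 0.8  # local median differs slightly

    def test_calm_nights_below_threshold(self, degraded_year):
        degraded, ledger, _ = degraded_year
        calm = ledger.calm_night_positions
        assert len(calm) > 0
        assert (degraded["ustar"].iloc[calm]
                < DegradationSpec().calm_ustar_threshold).all()

    def test_excessive_gaps_refused(self, default_year):
        series, truth = default_year
        spec = DegradationSpec(gap_fraction=0.99999, block_gap_lengths=(),
                               spike_count=0, calm_night_fraction=0.0,
                               suppress_low_ustar=False)
        with pytest.raises(ValueError, match="night"):
            degrade_series(series, truth, spec)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            DegradationSpec(gap_fraction=1.5)
        with pytest.raises(ValueError):
            DegradationSpec(spike_magnitude=0.0)

    def test_reproducible(self, default_year):
        series, truth = default_year
        a, la = degrade_series(series, truth, DegradationSpec(seed=3))
        b, lb = degrade_series(series, truth, DegradationSpec(seed=3))
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(la.gap_positions, lb.gap_positions)


class TestHighFrequencySimulation:
    def test_zero_target_near_zero_flux(self):
        block = simulate_high_frequency_block(0.0, n=18000, seed=0)
        assert abs(block_covariance_flux(block)) < 1.0

    def test_monte_carlo_mean_recovers_target(self):
        fluxes = [block_covariance_flux(
            simulate_high_frequency_block(-10.0, n=18000, seed=s))
            for s in range(200)]
        mean = np.mean(fluxes)
        se = np.std(fluxes, ddof=1) / np.sqrt(len(fluxes))
        assert abs(mean - (-10.0)) < 2 * se + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_high_frequency_block(-5.0, n=1)
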