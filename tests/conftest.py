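import numpy as np
import pandas as pd
import pytest

import caatingaflux as cf


@pytest.fixture(scope="session")
def default_year():
    """One noisy synthetic year with defaults (seed 1): (series, truth)."""
    return cf.simulate_year(cf.SiteConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_year():
    """A noise-free synthetic year: observed NEE equals reco - gpp exactly."""
    return cf.simulate_year(cf.SiteConfig(seed=3, noise_sd_nee=0.0))


@pytest.fixture(scope="session")
def degraded_year(default_year):
    """Default year after gap/spike/calm-night degradation, with ledger."""
    series, truth = default_year
    spec = cf.DegradationSpec(seed=2)
    degraded, ledger = cf.degrade_series(series, truth, spec)
    return degraded, ledger, truth


def make_night_series(n_days=60, seed=0, noise_sd=0.0, reco_ref=2.0, e0=150.0):
    """Nighttime-only records (22:00-05:00) with Lloyd-Taylor respiration.

    Used as a controlled input for E0 / base-respiration estimation tests.
    """
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2014-01-01 00:30", periods=n_days * 48, freq="30min")
    hour = (idx - pd.Timedelta(minutes=15)).hour
    night = (hour >= 22) | (hour < 5)
    seasonal = 6.0 * np.sin(2 * np.pi * np.arange(len(idx)) / (len(idx) / 2))
    ta = 22.0 + seasonal + rng.normal(0, 1.5, len(idx))
    p = cf.LloydTaylorParams(reco_ref=reco_ref, e0=e0)
    nee = cf.lloyd_taylor(ta, p) + rng.normal(0, noise_sd, len(idx))
    return (pd.Series(nee, index=idx)[night],
            pd.Series(ta, index=idx)[night], p)
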