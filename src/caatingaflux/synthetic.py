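"""Synthetic half-hourly meteorology and CO2 fluxes for a semiarid SDTF site.

Every downstream stage of the pipeline (QC, u*-filtering, gap-filling,
partitioning, aggregation) is exercised against data whose ground truth is
known.  The generator emulates the statistical structure of a seasonally dry
tropical forest tower site at low southern latitude: a Jan–May wet season
carrying nearly all of the ~500 mm annual rainfall, diurnal and seasonal
cycles of radiation and temperature, a vegetation-state (greenness) index
that follows antecedent rainfall with a configurable lag, respiration from
the Lloyd–Taylor temperature response scaled by vegetation state, and gross
uptake from a rectangular-hyperbola light response damped at high vapour
pressure deficit.  Observed NEE is respiration minus uptake plus Gaussian
noise; a separate degradation step injects gaps, spikes and calm (low
friction velocity) nights, keeping a complete ledger of every defect so
tests can assert exact recovery.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import LightResponseParams, LloydTaylorParams, lloyd_taylor
from .solar import clear_sky_rg

#: per-month relative weight of rain-day probability (Jan..Dec); the wet
#: season Jan–May carries nearly all events, peaking Feb–Apr.
MONTHLY_RAIN_WEIGHT = np.array(
    [0.55, 1.0, 1.2, 1.2, 0.75, 0.15, 0.08, 0.02, 0.02, 0.03, 0.06, 0.25])


def magnus_svp(t_c):
    """Saturation vapour pressure (kPa) via the Magnus formula.

    es(T) = 0.6112 * exp(17.62*T / (243.12 + T)), T in deg C.
    """
    t = np.asarray(t_c, dtype=float)
    return 0.6112 * np.exp(17.62 * t / (243.12 + t))


@dataclass
class SiteConfig:
    """Site and generator configuration.

    The defaults describe a Caatinga-like semiarid site: latitude ~6.6 deg S,
    ~513 mm annual rainfall concentrated between January and May, and a
    greenness index spanning 0.16–0.42.
    """

    latitude: float = -6.58
    year: int = 2014
    wet_season: tuple = ("01-01", "05-31")  # MM-DD interval
    annual_rain_target: float = 513.0  # mm
    veg_index_range: tuple = (0.16, 0.42)
    noise_sd_nee: float = 1.0  # µmol m-2 s-1
    noise_prop_nee: float = 0.0  # optional flux-proportional noise term
    seed: int = 0
    # meteorology shape parameters
    t_mean: float = 29.0  # deg C annual mean air temperature
    t_diurnal_amp: float = 5.5
    t_seasonal_amp: float = 1.5
    t_peak_doy: float = 330.0  # hottest time of year (pre-wet season)
    t_noise_sd: float = 0.8
    rain_day_cooling: float = 1.5  # deg C drop on rain days
    transmissivity: float = 0.75
    cloud_variability: float = 1.0  # 0 disables cloud modulation of R_g
    soil_t_offset: float = 2.5
    elevation_m: float = 205.0
    # vegetation-state dynamics
    veg_lag_days: float = 30.0
    # GPP modulation: uptake decays above vpd_crit with e-folding vpd_scale,
    # and an afternoon stomatal depression ramps in between pm_onset_hour and
    # pm_full_hour, reaching (1 - pm_depression)
    vpd_crit: float = 3.0  # kPa
    vpd_scale: float = 5.0  # kPa
    pm_depression: float = 0.8
    pm_onset_hour: float = 11.0
    pm_full_hour: float = 15.0
    veg_ref: float | None = None  # vegetation index mapping to scale 1.0

    def __post_init__(self):
        lo, hi = self.veg_index_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("veg_index_range must satisfy 0 < min < max < 1")
        if self.annual_rain_target <= 0:
            raise ValueError("annual_rain_target must be positive")
        if self.year <= 0:
            raise ValueError("year must be positive")
        start, end = self.wet_season
        if _mmdd(start) >= _mmdd(end):
            raise ValueError("wet_season interval must be increasing")
        if self.veg_ref is None:
            self.veg_ref = 0.5 * (lo + hi)


@dataclass
class TruthBundle:
    """Ground-truth flux components alongside the generating parameters."""

    true_gpp: pd.Series
    true_reco: pd.Series
    nee_observed: pd.Series
    lt: LloydTaylorParams
    lr: LightResponseParams
    config: SiteConfig


@dataclass
class DegradationSpec:
    """What to break: gaps, spikes and calm nights, all seeded."""

    gap_fraction: float = 0.10
    block_gap_lengths: tuple = (12, 48, 96)
    spike_count: int = 20
    spike_magnitude: float = 10.0  # multiples of the series MAD
    calm_night_fraction: float = 0.15
    calm_ustar_threshold: float = 0.25  # m s-1; NEE suppressed below this
    suppress_low_ustar: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in [0, 1)")
        if not (0.0 <= self.calm_night_fraction < 1.0):
            raise ValueError("calm_night_fraction must be in [0, 1)")
        if self.spike_magnitude <= 0:
            raise ValueError("spike_magnitude must be positive")


@dataclass
class DefectLedger:
    """Complete record of injected defects (integer positions)."""

    gap_positions: np.ndarray = field(default_factory=lambda: np.array([], int))
    spikes: list = field(default_factory=list)  # (position, injected delta)
    calm_night_positions: np.ndarray = field(default_factory=lambda: np.array([], int))
    suppressed_positions: np.ndarray = field(default_factory=lambda: np.array([], int))


def _mmdd(s: str) -> tuple:
    m, d = s.split("-")
    return int(m), int(d)


def _half_hour_index(year: int) -> pd.DatetimeIndex:
    """End-of-interval half-hourly timestamps covering one calendar year."""
    days = 366 if calendar.isleap(year) else 365
    return pd.date_range(start=f"{year}-01-01 00:30", periods=days * 48, freq="30min")


def simulate_met_year(config: SiteConfig) -> pd.DataFrame:
    """Generate one year of half-hourly meteorology.

    Returns a DataFrame indexed by end-of-interval timestamps with columns
    rg, ta, ts, rh, vpd, precip, ustar, pa, veg_index.  Radiation follows
    solar geometry at the site latitude modulated by daily cloudiness;
    rainfall is concentrated in the wet season and rescaled to the annual
    target; the vegetation index is a first-order (exponential) filter of
    daily rainfall rescaled into ``veg_index_range``.
    """
    rng = np.random.default_rng(config.seed)
    idx = _half_hour_index(config.year)
    n = len(idx)
    n_days = n // 48
    mid = idx - pd.Timedelta(minutes=15)  # interval midpoints
    doy = mid.dayofyear.to_numpy(dtype=float)
    hour = mid.hour.to_numpy() + mid.minute.to_numpy() / 60.0
    day_of_series = np.arange(n) // 48
    month_daily = idx[::48].month.to_numpy()

    # --- rainfall -----------------------------------------------------------
    p_rain = 0.45 * MONTHLY_RAIN_WEIGHT[month_daily - 1]
    is_rain_day = rng.random(n_days) < p_rain
    amounts = np.where(is_rain_day, rng.gamma(0.8, 12.0, size=n_days), 0.0)
    if amounts.sum() <= 0:  # pathological config: force one event
        amounts[n_days // 4] = 1.0
        is_rain_day[n_days // 4] = True
    amounts *= config.annual_rain_target / amounts.sum()

    precip = np.zeros(n)
    for d in np.flatnonzero(amounts > 0):
        k = 1 + rng.poisson(2)
        slots = rng.choice(48, size=min(k, 48), replace=False)
        split = rng.dirichlet(np.ones(len(slots)))
        precip[d * 48 + slots] += amounts[d] * split

    # --- vegetation-state index (first-order filter of daily rain) ---------
    veg_raw = np.empty(n_days)
    state = amounts[:30].mean() * config.veg_lag_days / 30.0 if n_days >= 30 else 0.0
    for d in range(n_days):
        state += (amounts[d] - state / config.veg_lag_days)
        veg_raw[d] = state
    lo, hi = config.veg_index_range
    span = veg_raw.max() - veg_raw.min()
    veg_daily = lo + (hi - lo) * ((veg_raw - veg_raw.min()) / span if span > 0
                                  else np.full(n_days, 0.5))
    veg = np.repeat(veg_daily, 48)
    veg_norm = (veg - lo) / (hi - lo)

    # --- radiation ----------------------------------------------------------
    if config.cloud_variability > 0:
        cloud_daily = np.where(is_rain_day,
                               rng.uniform(0.35, 0.75, n_days),
                               rng.uniform(0.75, 1.0, n_days))
        cloud_daily = 1.0 - config.cloud_variability * (1.0 - cloud_daily)
    else:
        cloud_daily = np.ones(n_days)
    rg = clear_sky_rg(config.latitude, doy, hour, config.transmissivity)
    rg = rg * np.repeat(cloud_daily, 48)

    # --- temperature --------------------------------------------------------
    seasonal = config.t_seasonal_amp * np.cos(
        2.0 * np.pi * (doy - config.t_peak_doy) / 365.25)
    diurnal = config.t_diurnal_amp * np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)
    day_offset = np.repeat(rng.normal(0.0, config.t_noise_sd, n_days), 48)
    cooling = config.rain_day_cooling * np.repeat(is_rain_day.astype(float), 48)
    ta = config.t_mean + seasonal + diurnal + day_offset - cooling
    ts = (pd.Series(ta).rolling(7, min_periods=1, center=True).mean().to_numpy()
          + config.soil_t_offset)

    # --- humidity -----------------------------------------------------------
    t_min_daily = pd.Series(ta).groupby(day_of_series).min().to_numpy()
    td = np.repeat(t_min_daily, 48) - 3.0 + 4.0 * veg_norm
    rh = np.clip(100.0 * magnus_svp(td) / magnus_svp(ta), 10.0, 98.0)
    vpd = magnus_svp(ta) * (1.0 - rh / 100.0)  # kPa

    # --- friction velocity and pressure ------------------------------------
    day_mask = rg >= 10.0
    ustar = np.where(day_mask,
                     rng.lognormal(np.log(0.38), 0.30, n),
                     rng.lognormal(np.log(0.22), 0.45, n))
    ustar = np.clip(ustar, 0.02, 1.5)
    pa = 101325.0 * np.exp(-config.elevation_m / 8434.0) + rng.normal(0.0, 50.0, n)

    return pd.DataFrame({
        "rg": rg, "ta": ta, "ts": ts, "rh": rh, "vpd": vpd,
        "precip": precip, "ustar": ustar, "pa": pa, "veg_index": veg,
    }, index=idx)


def simulate_true_fluxes(met: pd.DataFrame, lt: LloydTaylorParams,
                         lr: LightResponseParams,
                         config: SiteConfig) -> TruthBundle:
    """Generate true respiration/uptake and a noisy observed NEE series.

    R_eco is the Lloyd–Taylor response to air temperature scaled by the
    vegetation-state index (relative to ``config.veg_ref``); GPP is the
    rectangular-hyperbola light response scaled the same way and damped
    exponentially above a critical vapour pressure deficit; GPP is exactly
    zero wherever R_g = 0.  Observed NEE = R_eco - GPP + Gaussian noise.
    """
    required = {"rg", "ta", "vpd", "veg_index"}
    if not required.issubset(met.columns):
        raise ValueError(f"met must carry columns {sorted(required)}")
    if met[list(required)].isna().any().any():
        raise ValueError("met contains gaps; true fluxes need complete drivers")
    rng = np.random.default_rng(config.seed + 1)
    scale = met["veg_index"].to_numpy() / config.veg_ref
    reco = scale * np.asarray(lloyd_taylor(met["ta"].to_numpy(), lt))
    rg = met["rg"].to_numpy()
    hyp = np.where(rg > 0.0,
                   lr.alpha * lr.beta * rg / (lr.alpha * rg + lr.beta), 0.0)
    f_vpd = np.exp(-np.maximum(met["vpd"].to_numpy() - config.vpd_crit, 0.0)
                   / config.vpd_scale)
    mid = met.index - pd.Timedelta(minutes=15)
    hour = mid.hour.to_numpy() + mid.minute.to_numpy() / 60.0
    ramp = np.clip((hour - config.pm_onset_hour)
                   / max(config.pm_full_hour - config.pm_onset_hour, 1e-9),
                   0.0, 1.0)
    f_pm = 1.0 - config.pm_depression * ramp
    gpp = -hyp * scale * f_vpd * f_pm
    gpp = np.where(rg > 0.0, np.maximum(gpp, 0.0), 0.0)
    nee = reco - gpp
    if config.noise_sd_nee > 0 or config.noise_prop_nee > 0:
        sd = config.noise_sd_nee + config.noise_prop_nee * np.abs(nee)
        nee = nee + rng.normal(0.0, 1.0, len(nee)) * sd
    return TruthBundle(
        true_gpp=pd.Series(gpp, index=met.index, name="true_gpp"),
        true_reco=pd.Series(reco, index=met.index, name="true_reco"),
        nee_observed=pd.Series(nee, index=met.index, name="nee"),
        lt=lt, lr=lr, config=config)


def simulate_year(config: SiteConfig,
                  lt: LloydTaylorParams | None = None,
                  lr: LightResponseParams | None = None):
    """Convenience: met + fluxes in one call; returns (series, truth).

    The returned DataFrame is a complete half-hourly series (nee column
    included) ready for degradation or direct processing.
    """
    lt = lt or LloydTaylorParams(reco_ref=1.7, e0=150.0)
    lr = lr or LightResponseParams(alpha=-0.05, beta=-20.0, gamma=0.0)
    met = simulate_met_year(config)
    truth = simulate_true_fluxes(met, lt, lr, config)
    series = met.copy()
    series.insert(0, "nee", truth.nee_observed)
    return series, truth


def degrade_series(series: pd.DataFrame, truth: TruthBundle,
                   spec: DegradationSpec):
    """Inject gaps, spikes and calm nights; return (degraded, ledger).

    Calm nights: the requested fraction of nights gets friction velocity
    drawn below the configured threshold, and (optionally) all nighttime NEE
    at sub-threshold u* is linearly suppressed towards zero — emulating the
    flux-loss artefact that u*-filtering exists to remove.  Spikes are
    offsets of at least ``spike_magnitude`` series-MADs.  Gaps replace NEE by
    NaN as random singletons plus the requested contiguous blocks.
    """
    rng = np.random.default_rng(spec.seed)
    out = series.copy()
    n = len(out)
    nee = out["nee"].to_numpy(dtype=float).copy()
    night = out["rg"].to_numpy() < 10.0
    ledger = DefectLedger()

    # --- calm nights & low-u* suppression -----------------------------------
    ustar = out["ustar"].to_numpy(dtype=float).copy()
    if spec.calm_night_fraction > 0:
        day_ids = np.arange(n) // 48
        night_days = np.unique(day_ids[night])
        n_calm = int(round(spec.calm_night_fraction * len(night_days)))
        calm_days = rng.choice(night_days, size=n_calm, replace=False)
        calm_mask = np.isin(day_ids, calm_days) & night
        ustar[calm_mask] = rng.uniform(0.02, 0.8 * spec.calm_ustar_threshold,
                                       calm_mask.sum())
        ledger.calm_night_positions = np.flatnonzero(calm_mask)
    if spec.suppress_low_ustar:
        supp = night & (ustar < spec.calm_ustar_threshold)
        nee[supp] = nee[supp] * (ustar[supp] / spec.calm_ustar_threshold)
        ledger.suppressed_positions = np.flatnonzero(supp)
    out["ustar"] = ustar

    # --- spikes --------------------------------------------------------------
    mad = float(np.nanmedian(np.abs(nee - np.nanmedian(nee))))
    mad = mad if mad > 0 else 1.0
    if spec.spike_count > 0:
        pos = rng.choice(n, size=spec.spike_count, replace=False)
        sign = rng.choice([-1.0, 1.0], size=spec.spike_count)
        delta = sign * mad * (spec.spike_magnitude + rng.uniform(0.0, 5.0,
                                                                 spec.spike_count))
        nee[pos] += delta
        ledger.spikes = list(zip(pos.tolist(), delta.tolist()))

    # --- gaps ----------------------------------------------------------------
    n_gap_target = int(round(spec.gap_fraction * n))
    spike_pos = {p for p, _ in ledger.spikes}
    gap_mask = np.zeros(n, dtype=bool)
    for length in spec.block_gap_lengths:
        if gap_mask.sum() + length > n_gap_target:
            break
        start = int(rng.integers(0, n - length))
        gap_mask[start:start + length] = True
    remaining = n_gap_target - int(gap_mask.sum())
    if remaining > 0:
        candidates = np.flatnonzero(~gap_mask)
        candidates = candidates[~np.isin(candidates, list(spike_pos))]
        singles = rng.choice(candidates, size=min(remaining, len(candidates)),
                             replace=False)
        gap_mask[singles] = True
    if night.any() and not (night & ~gap_mask).any():
        raise ValueError("gap_fraction leaves no nighttime data; refusing")
    nee[gap_mask] = np.nan
    ledger.gap_positions = np.flatnonzero(gap_mask)

    out["nee"] = nee
    return out, ledger


def simulate_high_frequency_block(target_flux: float, rho_air: float = 40.0,
                                  n: int = 18000, seed: int = 0, *,
                                  sigma_w: float = 0.3, sigma_c: float = 2.0,
                                  c_mean: float = 400.0,
                                  sampling_rate: float = 10.0):
    """Draw one high-frequency block whose population covariance gives
    ``target_flux`` via rho_air * cov(w, c).

    c is built as a linear response to w plus independent noise, so
    cov(w, c) = target_flux / rho_air exactly in population; the empirical
    flux converges to the target as n grows.
    """
    from .fluxes import HighFrequencyBlock
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, sigma_w, n)
    slope = (target_flux / rho_air) / sigma_w ** 2
    c = c_mean + slope * w + rng.normal(0.0, sigma_c, n)
    return HighFrequencyBlock(w=w, c=c, rho_air=rho_air,
                              sampling_rate=sampling_rate)
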