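"""Nighttime-based flux partitioning into respiration and gross productivity.

By convention photosynthesis is off in the dark, so nighttime NEE equals
ecosystem respiration (R_eco).  Nighttime fluxes are regressed against air
temperature with the Lloyd–Taylor exponential model

    R_eco(T) = R_ref * exp(E0 * (1/(T_ref - T0) - 1/(T - T0)))

(temperatures in deg C; T_ref = 15, T0 = -42.02 by default).  The temperature
sensitivity E0 is estimated on sliding multi-day periods and combined into a
single annual value; the base respiration R_ref is then re-estimated on short
windows so that slow changes in substrate and canopy state are tracked.  The
fitted model extrapolates R_eco to daytime, and GPP follows from
NEE = R_eco - GPP (daytime) with GPP = 0 at night.

A rectangular-hyperbola light response NEE = a*b*Rg/(a*Rg + b) + g is fitted
to daytime data as a descriptive summary of canopy light use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class LloydTaylorParams:
    """Parameters of the exponential respiration-temperature response.

    ``reco_ref`` (µmol m-2 s-1) is respiration at ``t_ref``; ``e0`` (K) the
    temperature sensitivity; ``t0`` (deg C) the baseline temperature.
    """

    reco_ref: float = 2.0
    e0: float = 150.0
    t_ref: float = 15.0
    t0: float = -42.02

    def __post_init__(self):
        if self.reco_ref <= 0:
            raise ValueError("reco_ref must be positive")
        if self.e0 < 0:
            raise ValueError("e0 must be non-negative")
        if self.t0 >= self.t_ref:
            raise ValueError("t0 must lie below t_ref")


@dataclass
class LightResponseParams:
    """Rectangular-hyperbola light response parameters.

    ``alpha`` (µmol C J-1) initial slope, ``beta`` (µmol C m-2 s-1) uptake at
    light saturation, ``gamma`` (µmol C m-2 s-1) respiration offset; with the
    uptake-negative sign convention alpha and beta are negative.
    """

    alpha: float
    beta: float
    gamma: float
    rmse: float = float("nan")
    n: int = 0


@dataclass
class E0Estimate:
    value: float
    sd: float
    n_periods: int
    period_values: list = field(default_factory=list)


@dataclass
class PartitionResult:
    reco: pd.Series
    gpp: pd.Series
    reco_model: pd.Series
    n_clipped_gpp: int
    n_negative_night_reco: int


def lloyd_taylor(t_a, p: LloydTaylorParams):
    """Evaluate the respiration-temperature response at ``t_a`` (deg C).

    Strictly positive and increasing in temperature for e0 > 0.  Inputs that
    look like Kelvin (> 150) are rejected to catch unit mistakes.
    """
    t = np.asarray(t_a, dtype=float)
    if np.any(t > 150.0):
        raise ValueError("t_a looks like Kelvin; pass degrees Celsius")
    if np.any(t <= p.t0):
        raise ValueError(f"t_a must exceed t0={p.t0} degC")
    out = p.reco_ref * np.exp(p.e0 * (1.0 / (p.t_ref - p.t0) - 1.0 / (t - p.t0)))
    return out if out.ndim else float(out)


def _lt_shape(t, e0, t_ref, t0):
    return np.exp(e0 * (1.0 / (t_ref - t0) - 1.0 / (t - t0)))


def estimate_e0(nee_night: pd.Series, t_a_night: pd.Series, *,
                period_days: int = 15, shift_days: int = 5,
                accept: tuple = (30.0, 450.0), min_records: int = 6,
                min_t_range: float = 5.0, t_ref: float = 15.0,
                t0: float = -42.02) -> E0Estimate:
    """Estimate the annual temperature sensitivity E0 from nighttime data.

    Fits (R_ref, E0) by nonlinear least squares on each sliding period of
    ``period_days`` (stepped by ``shift_days``); periods with too few records,
    too little temperature leverage, an out-of-range E0 or an unusable
    uncertainty are discarded; survivors are combined by an
    inverse-variance-weighted mean.
    """
    df = pd.DataFrame({"nee": nee_night, "ta": t_a_night}).dropna()
    if df.empty:
        raise ValueError("no valid nighttime records")
    t_index = df.index
    start, end = t_index.min(), t_index.max()
    vals, sds = [], []
    period = pd.Timedelta(days=period_days)
    step = pd.Timedelta(days=shift_days)
    cur = start
    while cur <= end:
        sel = df[(t_index >= cur) & (t_index < cur + period)]
        cur = cur + step
        if len(sel) < min_records:
            continue
        t = sel["ta"].to_numpy()
        y = sel["nee"].to_numpy()
        if t.max() - t.min() < min_t_range:
            continue

        def model(tt, rref, e0):
            return rref * _lt_shape(tt, e0, t_ref, t0)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, t, y, p0=(max(y.mean(), 0.1), 100.0),
                                       bounds=([1e-6, 1.0], [50.0, 1000.0]),
                                       maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        e0_hat = popt[1]
        e0_sd = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
        if not (accept[0] <= e0_hat <= accept[1]) or not np.isfinite(e0_sd) or e0_sd <= 0:
            continue
        vals.append(float(e0_hat))
        sds.append(e0_sd)
    if not vals:
        raise ValueError("no period yielded an acceptable E0; "
                         "fall back to a fixed temperature sensitivity")
    w = 1.0 / np.square(sds)
    value = float(np.sum(w * np.asarray(vals)) / np.sum(w))
    sd = float(np.sqrt(1.0 / np.sum(w)))
    return E0Estimate(value=value, sd=sd, n_periods=len(vals), period_values=vals)


def estimate_reco_ref(nee_night: pd.Series, t_a_night: pd.Series, e0: float, *,
                      full_index: pd.DatetimeIndex, window_days: int = 4,
                      t_ref: float = 15.0, t0: float = -42.02,
                      floor: float = 0.05) -> pd.Series:
    """Base-respiration trajectory from nighttime fluxes with E0 held fixed.

    Within each ``window_days`` window the scale is the closed-form
    least-squares solution through the origin, sum(NEE*f)/sum(f^2) where f is
    the fixed-shape temperature response; window-centre values are linearly
    interpolated to every half hour and floored at a small positive value.
    """
    df = pd.DataFrame({"nee": nee_night, "ta": t_a_night}).dropna()
    if df.empty:
        raise ValueError("no valid nighttime records")
    centers, scales = [], []
    win = pd.Timedelta(days=window_days)
    cur = full_index.min()
    while cur <= full_index.max():
        sel = df[(df.index >= cur) & (df.index < cur + win)]
        if len(sel) >= 2:
            f = _lt_shape(sel["ta"].to_numpy(), e0, t_ref, t0)
            denom = float(np.sum(f * f))
            if denom > 0:
                scale = float(np.sum(sel["nee"].to_numpy() * f) / denom)
                centers.append(cur + win / 2)
                scales.append(max(scale, floor))
        cur = cur + win
    if not centers:
        raise ValueError("no window had enough nighttime records")
    traj = pd.Series(scales, index=pd.DatetimeIndex(centers))
    out = traj.reindex(traj.index.union(full_index)).interpolate(method="time")
    out = out.reindex(full_index).ffill().bfill()
    out.name = "reco_ref"
    return out


def compute_reco(t_a: pd.Series, e0: float, reco_ref: pd.Series, *,
                 t_ref: float = 15.0, t0: float = -42.02) -> pd.Series:
    """Modelled ecosystem respiration at every record."""
    shape = _lt_shape(t_a.to_numpy(dtype=float), e0, t_ref, t0)
    return pd.Series(reco_ref.to_numpy() * shape, index=t_a.index, name="reco_model")


def partition_nee(nee: pd.Series, reco_model: pd.Series,
                  night: pd.Series) -> PartitionResult:
    """Split gap-filled NEE into respiration and GPP series.

    Nighttime: GPP = 0 and R_eco = NEE (the measured flux *is* respiration);
    with noisy data a few nighttime records can therefore carry negative
    respiration — counted, not altered, so that NEE = R_eco - GPP stays exact
    at every record.  Daytime: GPP = R_eco,model - NEE; records where that is
    negative are clipped to GPP = 0 with R_eco set to NEE (count reported).
    The smooth model extrapolation is returned alongside as ``reco_model``.
    """
    night = night.astype(bool)
    nee_v = nee.to_numpy(dtype=float)
    model_v = reco_model.to_numpy(dtype=float)
    night_v = night.to_numpy()
    gpp = np.where(night_v, 0.0, model_v - nee_v)
    clipped = (~night_v) & (gpp < 0.0)
    gpp[clipped] = 0.0
    reco = nee_v + gpp  # identity NEE = reco - gpp holds by construction
    n_neg_night = int(np.sum(night_v & (reco < 0.0)))
    return PartitionResult(
        reco=pd.Series(reco, index=nee.index, name="reco"),
        gpp=pd.Series(gpp, index=nee.index, name="gpp"),
        reco_model=pd.Series(model_v, index=nee.index, name="reco_model"),
        n_clipped_gpp=int(clipped.sum()),
        n_negative_night_reco=n_neg_night,
    )


def light_response(rg, alpha, beta, gamma):
    """NEE predicted by the rectangular hyperbola at radiation ``rg``."""
    rg = np.asarray(rg, dtype=float)
    return alpha * beta * rg / (alpha * rg + beta) + gamma


def fit_light_response(nee_day: np.ndarray, rg_day: np.ndarray, *,
                       min_pairs: int = 30, min_rg_span: float = 300.0,
                       p0: tuple | None = None) -> LightResponseParams:
    """Fit the hyperbolic light response to daytime NEE vs global radiation.

    Starting values default to a data-driven guess (slope from the low-light
    records, saturation from the most negative decile).  Non-convergence
    raises with diagnostics; there are no silent fallback parameters.
    """
    nee = np.asarray(nee_day, dtype=float)
    rg = np.asarray(rg_day, dtype=float)
    ok = np.isfinite(nee) & np.isfinite(rg)
    nee, rg = nee[ok], rg[ok]
    if len(nee) < min_pairs:
        raise ValueError(f"need >= {min_pairs} daytime pairs, got {len(nee)}")
    if rg.max() - rg.min() < min_rg_span:
        raise ValueError(f"R_g span {rg.max() - rg.min():.0f} W m-2 below "
                         f"required {min_rg_span:.0f}")
    if p0 is None:
        beta0 = min(np.quantile(nee, 0.05), -1.0)
        p0 = (-0.03, beta0, max(np.median(nee[rg < np.quantile(rg, 0.1)]), 0.1))
    try:
        popt, _ = curve_fit(light_response, rg, nee, p0=p0, maxfev=5000)
    except RuntimeError as exc:
        raise RuntimeError(f"light-response fit did not converge (n={len(nee)}, "
                           f"p0={p0}): {exc}") from exc
    resid = nee - light_response(rg, *popt)
    params = LightResponseParams(alpha=float(popt[0]), beta=float(popt[1]),
                                 gamma=float(popt[2]),
                                 rmse=float(np.sqrt(np.mean(resid ** 2))),
                                 n=len(nee))
    if abs(params.beta) >= 100.0:
        raise RuntimeError(f"implausible saturation uptake beta={params.beta:.1f}")
    return params
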