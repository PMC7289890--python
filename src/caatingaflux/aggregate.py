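"""Seasonal and annual carbon accounting with bootstrap uncertainty.

Half-hourly fluxes (µmol CO2 m-2 s-1, uptake negative) are converted to
carbon mass (g C m-2) with the molar mass of carbon, summed to daily and
seasonal totals over a four-season calendar (wet, wet-dry transition, dry,
dry-wet transition), and summarised as mean daily flux +/- sd, cumulative
sums, the ecosystem carbon-use efficiency NEP/GPP (net ecosystem production
NEP = -NEE), clock-window means (e.g. midday 10:00-12:00), percentile
bootstrap confidence intervals, and Pearson correlation matrices against
the meteorological drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CARBON_MOLAR_MASS = 12.011  # g mol-1
SECONDS_HALF_HOUR = 1800.0


@dataclass
class SeasonCalendar:
    """Non-overlapping MM-DD intervals labelling every day of the year.

    The default reflects a semiarid rainfall regime: wet Jan 15 - May 31,
    wet-dry Jun 1 - Jul 31, dry Aug 1 - Nov 30, dry-wet Dec 1 - Jan 14 (the
    dry-wet transition wraps the turn of the year).
    """

    intervals: dict = field(default_factory=lambda: {
        "wet": ("01-15", "05-31"),
        "wet-dry": ("06-01", "07-31"),
        "dry": ("08-01", "11-30"),
        "dry-wet": ("12-01", "01-14"),
    })

    def __post_init__(self):
        # verify the union covers all days exactly once
        probe = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        labels = self.labels(probe)
        if labels.isna().any():
            raise ValueError("season intervals do not cover the full year")

    def labels(self, index: pd.DatetimeIndex) -> pd.Series:
        mmdd = index.strftime("%m-%d")
        out = pd.Series(pd.NA, index=index, dtype=object)
        for name, (start, end) in self.intervals.items():
            if start <= end:
                mask = (mmdd >= start) & (mmdd <= end)
            else:  # wraps the year boundary
                mask = (mmdd >= start) | (mmdd <= end)
            if (out[mask].notna()).any():
                raise ValueError(f"season {name} overlaps another interval")
            out[mask] = name
        return out

    @property
    def names(self):
        return list(self.intervals)


def umol_to_gc(flux, dt: float = SECONDS_HALF_HOUR):
    """Convert a CO2 flux in µmol m-2 s-1 over ``dt`` seconds to g C m-2."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.asarray(flux, dtype=float) * dt * CARBON_MOLAR_MASS * 1e-6


def gc_to_umol(mass, dt: float = SECONDS_HALF_HOUR):
    """Inverse of :func:`umol_to_gc` (used for round-trip checks)."""
    return np.asarray(mass, dtype=float) / (dt * CARBON_MOLAR_MASS * 1e-6)


def daily_sums(series: pd.Series) -> pd.Series:
    """Daily carbon totals (g C m-2 d-1) from half-hourly fluxes.

    Days with missing half hours are prorated (scaled by 48/n_valid) and
    counted in the log; fully missing days yield NaN.
    """
    mass = pd.Series(umol_to_gc(series.to_numpy()), index=series.index)
    # end-of-interval convention: the record stamped 00:00 closes the
    # previous day, so group by the interval midpoint's date
    grouped = mass.groupby((mass.index - pd.Timedelta(minutes=15)).date)
    sums = grouped.sum(min_count=1)
    counts = grouped.count()
    incomplete = (counts > 0) & (counts < 48)
    if incomplete.any():
        logger.info("%d incomplete days prorated into daily sums",
                    int(incomplete.sum()))
        sums[incomplete] = sums[incomplete] * 48.0 / counts[incomplete]
    sums.index = pd.DatetimeIndex(sums.index)
    return sums


def seasonal_summary(series: pd.Series, calendar: SeasonCalendar | None = None,
                     *, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-season and annual daily-mean, sd, cumulative sum and bootstrap CI.

    Returns one row per season plus ``annual``; the annual sum equals the
    sum of the seasonal sums exactly (the seasons partition the year).
    """
    calendar = calendar or SeasonCalendar()
    daily = daily_sums(series).dropna()
    labels = calendar.labels(daily.index)
    rng = np.random.default_rng(seed)
    rows = {}
    for name in calendar.names + ["annual"]:
        vals = daily.to_numpy() if name == "annual" \
            else daily[labels == name].to_numpy()
        if len(vals) == 0:
            continue
        mean, lo, hi = bootstrap_ci(vals, n_boot=n_boot,
                                    rng=np.random.default_rng(rng.integers(2**31)))
        rows[name] = {
            "mean_daily": float(vals.mean()),
            "sd_daily": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "sum": float(vals.sum()),
            "ci_lo": lo, "ci_hi": hi, "n_days": len(vals),
        }
    return pd.DataFrame(rows).T


def carbon_use_efficiency(nee_sum: float, gpp_sum: float) -> float:
    """NEP/GPP ratio from signed annual sums (uptake negative), 2 decimals.

    NEP = -NEE, and GPP enters by magnitude, so the ratio is
    (-nee_sum)/(-gpp_sum); it is scale-invariant and equals 1 when all
    assimilated carbon is retained.
    """
    if gpp_sum == 0:
        raise ValueError("GPP sum is zero; carbon-use efficiency undefined")
    return round((-nee_sum) / (-gpp_sum), 2)


def window_mean(series: pd.Series, clock_window: tuple = ("10:00", "12:00"),
                calendar: SeasonCalendar | None = None) -> pd.DataFrame:
    """Mean +/- sd inside a clock-time window, per season and annually.

    With end-of-interval timestamps a record belongs to the window when its
    interval midpoint falls inside [start, end); windows may wrap midnight
    (e.g. 22:00-00:00 for the nighttime window).
    """
    calendar = calendar or SeasonCalendar()
    start = pd.Timedelta(clock_window[0] + ":00")
    end = pd.Timedelta(clock_window[1] + ":00")
    if end == pd.Timedelta(0):
        end = pd.Timedelta(hours=24)
    if end <= start:
        end += pd.Timedelta(hours=24)
    mid = series.index - pd.Timedelta(minutes=15)
    tod = pd.to_timedelta(mid.hour * 60 + mid.minute, unit="m")
    in_win = ((tod >= start) & (tod < end)) | \
             ((tod + pd.Timedelta(hours=24) >= start)
              & (tod + pd.Timedelta(hours=24) < end))
    sel = series[in_win].dropna()
    if sel.empty:
        raise ValueError("clock window selects no records")
    labels = calendar.labels(sel.index)
    rows = {}
    for name in calendar.names:
        vals = sel[labels == name]
        if len(vals):
            rows[name] = {"mean": vals.mean(),
                          "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                          "n": len(vals)}
    rows["annual"] = {"mean": sel.mean(), "sd": sel.std(ddof=1), "n": len(sel)}
    return pd.DataFrame(rows).T


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int | None = None, rng=None):
    """Percentile bootstrap CI of the mean; returns (mean, lo, hi).

    Fewer than 3 values yield (mean, nan, nan) — flagged, not fatal.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan"), float("nan"), float("nan")
    mean = float(vals.mean())
    if len(vals) < 3:
        logger.warning("bootstrap needs >= 3 values; CI undefined")
        return mean, float("nan"), float("nan")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return mean, float(lo), float(hi)


def ci_overlap(ci_a: tuple, ci_b: tuple) -> bool:
    """Whether two (lo, hi) intervals overlap — the significance rule used
    for comparing seasonal means."""
    return not (ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0])


def correlation_matrix(df: pd.DataFrame, *, min_obs: int = 10,
                       alpha: float = 0.05):
    """Pairwise Pearson correlations with two-sided p-values.

    Returns (r, p) DataFrames; zero-variance or data-poor pairs yield NaN
    with a warning.  The diagonal is exactly 1.
    """
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = df[[a, b]].dropna()
            if len(pair) < min_obs or pair[a].std() == 0 or pair[b].std() == 0:
                logger.warning("correlation %s~%s undefined (n=%d)", a, b,
                               len(pair))
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
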