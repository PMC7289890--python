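"""Quality control: despiking, nighttime flagging and u* threshold filtering.

Spurious half-hourly fluxes are removed by separating each series into a
smooth part (a centred moving median) and a residual part; residuals larger
than ``z_threshold`` robust standard deviations (1.4826 x the moving MAD)
are spikes.  Nighttime records with weak turbulence under-measure the true
efflux, so nighttime NEE below a friction-velocity threshold is rejected;
the threshold is found by the moving point test (MPT): within each season
and air-temperature class, fluxes are binned by u* and the threshold is the
first u* class whose mean flux reaches 95% of the mean of all higher
classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: QC flag values written to the half-hourly table
FLAG_OK = 0
FLAG_SPIKE = 1
FLAG_LOW_USTAR = 2
FLAG_MISSING = 9


@dataclass
class DespikeConfig:
    window: int = 49  # half hours, odd
    z_threshold: float = 7.0  # multiples of the scaled MAD
    max_passes: int = 10

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class UStarResult:
    """Per-season u* thresholds plus the class diagnostics behind them."""

    thresholds: dict  # season label -> m s-1
    classes: dict = field(default_factory=dict)  # season -> per-T-class detail
    accepted_range: tuple = (0.18, 0.34)
    fallback_used: bool = False


def flag_nighttime(series: pd.DataFrame, rg_threshold: float = 10.0) -> pd.Series:
    """Boolean night mask: R_g below ``rg_threshold`` W m-2.

    Records with missing R_g are flagged night=False but reported; callers
    that need three-state logic can test ``series['rg'].isna()`` directly.
    """
    if "rg" not in series.columns:
        raise ValueError("series must carry an 'rg' column")
    rg = series["rg"]
    n_unknown = int(rg.isna().sum())
    if n_unknown:
        logger.warning("%d records have missing R_g; treated as daytime", n_unknown)
    return (rg < rg_threshold).fillna(False)


def despike_moving_median(values: pd.Series, cfg: DespikeConfig | None = None):
    """Moving-median despiking; returns (clean series, spike mask).

    Iterates until no new spikes are found or ``max_passes`` is reached;
    flagged records are replaced by NaN (to be gap-filled later, never
    interpolated here).  Windows with zero MAD flag nothing.  Series shorter
    than the window fall back to a single global-median pass.
    """
    cfg = cfg or DespikeConfig()
    clean = values.astype(float).copy()
    spike_mask = pd.Series(False, index=values.index)
    short = len(values) < cfg.window
    for _ in range(cfg.max_passes):
        if short:
            med = pd.Series(clean.median(), index=clean.index)
            resid = clean - med
            rmed = pd.Series(resid.median(), index=clean.index)
            mad = pd.Series((resid - rmed).abs().median(), index=clean.index)
        else:
            roll = clean.rolling(cfg.window, center=True, min_periods=3)
            med = roll.median()
            resid = clean - med
            rroll = resid.rolling(cfg.window, center=True, min_periods=3)
            rmed = rroll.median()
            mad = (resid - rmed).abs().rolling(cfg.window, center=True,
                                               min_periods=3).median()
        sigma = 1.4826 * mad
        new = (sigma > 0) & ((resid - rmed).abs() > cfg.z_threshold * sigma)
        new = new.fillna(False) & ~spike_mask
        if not new.any():
            break
        spike_mask |= new
        clean[new] = np.nan
    return clean, spike_mask


def _season_of(index: pd.DatetimeIndex, calendar_intervals) -> pd.Series:
    """Map timestamps to season labels via an aggregate.SeasonCalendar."""
    from .aggregate import SeasonCalendar
    if calendar_intervals is None:
        calendar_intervals = SeasonCalendar()
    return calendar_intervals.labels(index)


def ustar_threshold_mpt(series: pd.DataFrame, night: pd.Series, *,
                        seasons: pd.Series | None = None,
                        n_temp_classes: int = 6, n_ustar_classes: int = 20,
                        ratio: float = 0.95, floor: float = 0.05,
                        min_records: int = 200,
                        default_threshold: float = 0.25) -> UStarResult:
    """Moving point test on nighttime data; one u* threshold per season.

    Within a season, valid nighttime records are split into
    ``n_temp_classes`` air-temperature quantile classes, each into
    ``n_ustar_classes`` u* quantile classes.  A temperature class's
    threshold is the mean u* of the lowest u* class whose mean NEE reaches
    ``ratio`` of the mean NEE of all higher u* classes; the season threshold
    is the median over temperature classes, floored at ``floor``.  Seasons
    with fewer than ``min_records`` valid nights fall back to
    ``default_threshold`` with a warning.
    """
    df = pd.DataFrame({
        "nee": series["nee"], "ustar": series["ustar"], "ta": series["ta"],
    })[night.values if isinstance(night, pd.Series) else night].dropna()
    if seasons is None:
        seasons = _season_of(df.index, None)
    else:
        seasons = seasons.loc[df.index]
    thresholds, details = {}, {}
    fallback = False
    for label, grp in df.groupby(seasons, observed=True):
        if len(grp) < min_records:
            logger.warning("season %s: only %d nighttime records; using "
                           "default u* threshold %.2f", label, len(grp),
                           default_threshold)
            thresholds[label] = default_threshold
            fallback = True
            continue
        t_classes = pd.qcut(grp["ta"], n_temp_classes, labels=False,
                            duplicates="drop")
        class_thresholds = []
        class_detail = []
        for _, tgrp in grp.groupby(t_classes):
            if len(tgrp) < 2 * n_ustar_classes:
                continue
            u_classes = pd.qcut(tgrp["ustar"], n_ustar_classes, labels=False,
                                duplicates="drop")
            means = tgrp.groupby(u_classes).agg(
                nee=("nee", "mean"), ustar=("ustar", "mean"))
            k = len(means)
            thr = float(means["ustar"].iloc[-1])  # default: highest class
            for i in range(k - 1):
                higher = means["nee"].iloc[i + 1:].mean()
                if higher != 0 and means["nee"].iloc[i] >= ratio * higher:
                    thr = float(means["ustar"].iloc[i])
                    break
            class_thresholds.append(thr)
            class_detail.append(means)
        if not class_thresholds:
            thresholds[label] = default_threshold
            fallback = True
            continue
        thresholds[label] = max(float(np.median(class_thresholds)), floor)
        details[label] = class_detail
    result = UStarResult(thresholds=thresholds, classes=details,
                         fallback_used=fallback)
    for label, thr in thresholds.items():
        inside = result.accepted_range[0] <= thr <= result.accepted_range[1]
        logger.info("u* threshold %s: %.3f m s-1 (%s the site validity "
                    "interval %.2f-%.2f)", label, thr,
                    "inside" if inside else "outside", *result.accepted_range)
    return result


def apply_ustar_filter(series: pd.DataFrame, result: UStarResult,
                       night: pd.Series, *,
                       seasons: pd.Series | None = None):
    """Reject nighttime NEE measured below the season's u* threshold.

    Daytime records are never modified.  Returns (filtered series, rejection
    mask); rejected NEE becomes NaN for subsequent gap-filling.
    """
    out = series.copy()
    if seasons is None:
        seasons = _season_of(out.index, None)
    thr = seasons.map(result.thresholds).astype(float)
    night_arr = night.values if isinstance(night, pd.Series) else night
    reject = pd.Series(night_arr & (out["ustar"].to_numpy() < thr.to_numpy())
                       & out["nee"].notna().to_numpy(), index=out.index)
    out.loc[reject, "nee"] = np.nan
    logger.info("u* filter rejected %d nighttime records", int(reject.sum()))
    return out, reject
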