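"""Half-hourly CSV dialect, pipeline configuration, and stage chaining.

The exchange format is a plain CSV with an ISO-8601 ``timestamp`` column
(local standard time, end-of-interval convention) and a configurable
missing-value sentinel (default -9999, the common flux-tower convention).
On read the series is regularised onto a strict 30-min grid: absent half
hours become all-missing rows, and duplicate or decreasing timestamps are a
hard error.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import yaml

from . import aggregate, gapfill, partition, qc, synthetic

logger = logging.getLogger(__name__)

SENTINEL = -9999.0
DATA_COLUMNS = ["nee", "rg", "ta", "ts", "rh", "vpd", "precip", "ustar", "pa"]


def write_half_hourly(df: pd.DataFrame, path, sentinel: float = SENTINEL):
    """Write the half-hourly table with NaN mapped to the sentinel."""
    out = df.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    for col in out.columns:
        if col == "timestamp":
            continue
        if out[col].dtype.kind == "f":
            out[col] = out[col].where(np.isfinite(out[col]), sentinel)
    out.to_csv(path, index=False)


def read_half_hourly(path, sentinel: float = SENTINEL) -> pd.DataFrame:
    """Read the half-hourly CSV, mapping the sentinel to missing and
    regularising the timestamp grid.

    Raises on duplicate or decreasing timestamps, naming the offending
    rows; a malformed timestamp raises with its line number.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: no 'timestamp' column")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = None
        for lineno, raw in enumerate(df["timestamp"], start=2):
            try:
                pd.to_datetime(raw)
            except (ValueError, TypeError):
                bad = lineno
                break
        raise ValueError(f"{path}: malformed timestamp at line {bad}") from exc
    if ts.duplicated().any():
        rows = (ts[ts.duplicated()].index + 2).tolist()
        raise ValueError(f"{path}: duplicate timestamps at rows {rows}")
    if not ts.is_monotonic_increasing:
        rows = (ts[ts.diff() < pd.Timedelta(0)].index + 2).tolist()
        raise ValueError(f"{path}: decreasing timestamps at rows {rows}")
    df = df.drop(columns="timestamp")
    df.index = pd.DatetimeIndex(ts)
    df = df.replace(sentinel, np.nan)
    full = pd.date_range(df.index.min(), df.index.max(), freq="30min")
    if len(full) != len(df):
        logger.info("regularised grid: %d rows inserted as missing",
                    len(full) - len(df))
    return df.reindex(full)


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the processing chain in one declarative document."""

    site: synthetic.SiteConfig = dataclasses.field(
        default_factory=synthetic.SiteConfig)
    degradation: synthetic.DegradationSpec = dataclasses.field(
        default_factory=synthetic.DegradationSpec)
    despike: qc.DespikeConfig = dataclasses.field(
        default_factory=qc.DespikeConfig)
    mds: gapfill.MdsTolerances = dataclasses.field(
        default_factory=gapfill.MdsTolerances)
    seasons: aggregate.SeasonCalendar = dataclasses.field(
        default_factory=aggregate.SeasonCalendar)
    rg_night_threshold: float = 10.0
    e0_period_days: int = 15
    e0_shift_days: int = 5
    reco_ref_window_days: int = 4
    midday_window: tuple = ("10:00", "12:00")
    night_window: tuple = ("22:00", "00:00")
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(doc) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        nested = {"site": synthetic.SiteConfig,
                  "degradation": synthetic.DegradationSpec,
                  "despike": qc.DespikeConfig,
                  "mds": gapfill.MdsTolerances}
        for key, val in doc.items():
            if key in nested and isinstance(val, dict):
                sub = nested[key]
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(val) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {key} keys: {sorted(sub_unknown)}")
                for k in ("wet_season", "veg_index_range", "block_gap_lengths",
                          "window_ladder", "diurnal_ladder"):
                    if k in val and isinstance(val[k], list):
                        val[k] = tuple(val[k])
                kwargs[key] = sub(**val)
            elif key == "seasons" and isinstance(val, dict):
                kwargs[key] = aggregate.SeasonCalendar(
                    intervals={k: tuple(v) for k, v in val.items()})
            else:
                kwargs[key] = tuple(val) if key.endswith("window") else val
        return cls(**kwargs)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, series: pd.DataFrame) -> dict:
    """Run QC -> u* filter -> gap-fill -> partition -> aggregate.

    Returns a dict of stage outputs: the processed table (with qc/fill
    flags, reco and gpp columns), the u* result, the E0 estimate, the
    seasonal summaries and window means, plus per-stage record counts.
    Deterministic under a fixed config.
    """
    logger.info("resolved config: %s", config.resolved())
    counts = {"input": len(series)}
    table = series.copy()
    qc_flag = pd.Series(qc.FLAG_OK, index=table.index, dtype=int)
    qc_flag[table["nee"].isna()] = qc.FLAG_MISSING

    # stage 1: despike
    clean, spikes = qc.despike_moving_median(table["nee"], config.despike)
    table["nee"] = clean
    qc_flag[spikes] = qc.FLAG_SPIKE
    counts["spikes_removed"] = int(spikes.sum())

    # stage 2: u* threshold and nighttime filtering
    night = qc.flag_nighttime(table, config.rg_night_threshold)
    seasons = config.seasons.labels(table.index)
    ustar_result = qc.ustar_threshold_mpt(table, night, seasons=seasons)
    table, rejected = qc.apply_ustar_filter(table, ustar_result, night,
                                            seasons=seasons)
    qc_flag[rejected] = qc.FLAG_LOW_USTAR
    counts["low_ustar_rejected"] = int(rejected.sum())

    # stage 3: gap-fill meteorology then NEE
    table = gapfill.fill_meteorology(table)
    fill = gapfill.mds_fill(table, config.mds)
    table = fill.series
    counts["gaps_filled"] = fill.n_filled
    for grade in "ABC":
        counts[f"fill_grade_{grade}"] = int((fill.fill_flag == grade).sum())

    # stage 4: partition
    observed_night = night & (fill.fill_flag == "observed")
    e0 = partition.estimate_e0(table.loc[observed_night, "nee"],
                               table.loc[observed_night, "ta"],
                               period_days=config.e0_period_days,
                               shift_days=config.e0_shift_days)
    rref = partition.estimate_reco_ref(table.loc[observed_night, "nee"],
                                       table.loc[observed_night, "ta"],
                                       e0.value, full_index=table.index,
                                       window_days=config.reco_ref_window_days)
    reco_model = partition.compute_reco(table["ta"], e0.value, rref)
    part = partition.partition_nee(table["nee"], reco_model, night)
    table["reco"] = part.reco
    table["gpp"] = part.gpp
    table["qc_flag"] = qc_flag
    table["fill_flag"] = fill.fill_flag
    counts["gpp_clipped"] = part.n_clipped_gpp

    # stage 5: aggregate
    summaries = {var: aggregate.seasonal_summary(
        table[var], config.seasons, n_boot=config.n_boot, seed=config.seed)
        for var in ("nee", "gpp", "reco")}
    cue = aggregate.carbon_use_efficiency(
        summaries["nee"].loc["annual", "sum"],
        -abs(summaries["gpp"].loc["annual", "sum"]))
    midday = aggregate.window_mean(table["nee"], config.midday_window,
                                   config.seasons)
    night_mean = aggregate.window_mean(table["nee"], config.night_window,
                                       config.seasons)
    return {
        "table": table, "ustar": ustar_result, "e0": e0, "reco_ref": rref,
        "summaries": summaries, "cue": cue, "midday": midday,
        "night": night_mean, "counts": counts, "fill": fill,
    }
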