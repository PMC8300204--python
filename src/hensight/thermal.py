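"""Temperature-humidity index (THI) and thermal-comfort classification.

THI combines dry-bulb temperature ``T`` (deg C) and relative humidity
``RH`` (%) into a single heat-load scalar::

    THI = 0.8 T + RH (T - 14.3) / 100 + 46.3

For laying hens the thermoneutral zone is bounded by THI 59 (cold
stress below) and THI 78 (heat stress above); the corresponding air
temperature limits are 15 and 28 deg C. Thresholds are strict
inequalities ("above" / "below"), so a value exactly on a limit
classifies as comfort. Hourly aggregation computes the THI of the
hourly-mean temperature and humidity.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThermalRecord",
    "ComfortThresholds",
    "ComfortClass",
    "thi",
    "classify_comfort",
    "hourly_means",
    "label_recordings",
]


class ComfortClass(str, enum.Enum):
    COLD = "cold"
    COMFORT = "comfort"
    HEAT = "heat"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class ThermalRecord:
    """One datalogger sample: timestamp, dry-bulb T (deg C), RH (%)."""

    timestamp: pd.Timestamp
    temp_c: float
    rh_pct: float

    def __post_init__(self) -> None:
        if not 0 <= self.rh_pct <= 100:
            raise ValueError("relative humidity must lie in [0, 100] %")
        if not -20 < self.temp_c < 60:
            raise ValueError("temperature outside the physical range (-20, 60) C")


@dataclass(frozen=True)
class ComfortThresholds:
    """Class limits; defaults are the laying-hen literature values."""

    thi_cold: float = 59.0
    thi_heat: float = 78.0
    t_cold: float = 15.0
    t_heat: float = 28.0

    def __post_init__(self) -> None:
        if not self.thi_cold < self.thi_heat:
            raise ValueError("thi_cold must be < thi_heat")
        if not self.t_cold < self.t_heat:
            raise ValueError("t_cold must be < t_heat")


def thi(T, RH):
    """Temperature-humidity index; accepts scalars or arrays.

    Strictly increasing in ``T`` at any valid humidity; increasing in
    ``RH`` only above 14.3 deg C (the humidity term changes sign there).
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(RH < 0) or np.any(RH > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = 0.8 * T + RH * (T - 14.3) / 100.0 + 46.3
    return float(out) if out.ndim == 0 else out


def classify_comfort(
    thi_value: float,
    T_mean: float | None = None,
    thresholds: ComfortThresholds = ComfortThresholds(),
    rule: Literal["thi_only", "thi_or_temp"] = "thi_only",
) -> ComfortClass:
    """Assign a cold / comfort / heat label to an observation window.

    ``thi_only`` (default) uses the THI limits alone; ``thi_or_temp``
    additionally triggers heat above ``t_heat`` and cold below
    ``t_cold`` (requires ``T_mean``). Boundaries are strict: equality
    with a limit is comfort.
    """
    if not np.isfinite(thi_value):
        raise ValueError("THI must be finite")
    th = thresholds
    heat = thi_value > th.thi_heat
    cold = thi_value < th.thi_cold
    if rule == "thi_or_temp":
        if T_mean is None:
            raise ValueError("rule 'thi_or_temp' requires T_mean")
        heat = heat or T_mean > th.t_heat
        cold = cold or T_mean < th.t_cold
    elif rule != "thi_only":
        raise ValueError(f"unknown classification rule {rule!r}")
    if heat and cold:  # only reachable with pathological thresholds
        raise ValueError("window classifies as both heat and cold")
    if heat:
        return ComfortClass.HEAT
    if cold:
        return ComfortClass.COLD
    return ComfortClass.COMFORT


def hourly_means(records: pd.DataFrame) -> pd.DataFrame:
    """Hourly mean T and RH plus the THI of those means.

    ``records`` needs columns ``timestamp, temp_c, rh_pct``, sorted in
    time. Hours with no records are simply absent. Returns columns
    ``hour, temp_c, rh_pct, thi, n_records``.
    """
    required = {"timestamp", "temp_c", "rh_pct"}
    if missing := required - set(records.columns):
        raise ValueError(f"thermal log lacks columns {sorted(missing)}")
    ts = pd.to_datetime(records["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("thermal log must be sorted by timestamp")
    df = records.assign(hour=ts.dt.floor("h"))
    agg = (
        df.groupby("hour", sort=True)
        .agg(temp_c=("temp_c", "mean"), rh_pct=("rh_pct", "mean"), n_records=("temp_c", "size"))
        .reset_index()
    )
    agg["thi"] = thi(agg["temp_c"].to_numpy(), agg["rh_pct"].to_numpy())
    return agg[["hour", "temp_c", "rh_pct", "thi", "n_records"]]


def label_recordings(
    windows: pd.DataFrame,
    hourly: pd.DataFrame,
    thresholds: ComfortThresholds = ComfortThresholds(),
    rule: Literal["thi_only", "thi_or_temp"] = "thi_only",
) -> pd.DataFrame:
    """Comfort label per recording window from the hourly THI table.

    ``windows`` needs columns ``recording_id, start, end``; each window
    is labelled by classifying the mean THI (and mean T, for the
    combined rule) of the logged hours its span overlaps. Windows with
    no thermal coverage are labelled ``missing`` and logged; downstream
    aggregation excludes them.

    Returns columns ``recording_id, comfort, thi_mean, temp_mean``.
    """
    if missing := {"recording_id", "start", "end"} - set(windows.columns):
        raise ValueError(f"windows table lacks columns {sorted(missing)}")
    hours = pd.to_datetime(hourly["hour"])
    rows = []
    n_missing = 0
    for rec in windows.itertuples(index=False):
        start = pd.Timestamp(rec.start)
        end = pd.Timestamp(rec.end)
        sel = (hours < end) & (hours + pd.Timedelta(hours=1) > start)
        if not sel.any():
            n_missing += 1
            rows.append((rec.recording_id, "missing", np.nan, np.nan))
            continue
        thi_mean = float(hourly.loc[sel.to_numpy(), "thi"].mean())
        t_mean = float(hourly.loc[sel.to_numpy(), "temp_c"].mean())
        label = classify_comfort(thi_mean, t_mean, thresholds, rule)
        rows.append((rec.recording_id, str(label), thi_mean, t_mean))
    if n_missing:
        logger.warning(
            "label_recordings: %d of %d windows had no thermal coverage",
            n_missing,
            len(windows),
        )
    return pd.DataFrame(rows, columns=["recording_id", "comfort", "thi_mean", "temp_mean"])
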