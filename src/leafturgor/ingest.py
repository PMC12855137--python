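"""Logger-data ingestion: VPD computation, soil-water interpolation, merging.

The probe logger and the greenhouse weather station both record on a
5-minute grid; soil water content (SWC, volumetric %, 0-60 cm profile
mean) is observed only every few days. This module reads those CSVs,
derives vapour pressure deficit from temperature and relative humidity,
linearly interpolates SWC to daily values (held constant within each
calendar day), and merges everything onto a single 5-minute grid per
treatment.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import COLUMN_ORDER, GRID_MINUTES

log = logging.getLogger(__name__)

_T_MIN, _T_MAX = -20.0, 60.0


def compute_vpd(T, RH):
    """Vapour pressure deficit (kPa) from air temperature and humidity.

    VPD = 0.611 * exp(17.502*T / (T + 240.97)) * (1 - RH/100)

    with T in deg C and RH in percent (0-100). Saturated air (RH = 100)
    gives exactly 0. Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If RH falls outside [0, 100] or T outside the physically
        plausible range (-20, 60) deg C.
    """
    T_arr = np.asarray(T, dtype=float)
    RH_arr = np.asarray(RH, dtype=float)
    if np.any((RH_arr < 0.0) | (RH_arr > 100.0)):
        bad = RH_arr[(RH_arr < 0.0) | (RH_arr > 100.0)]
        raise ValueError(
            f"relative humidity must lie in [0, 100] %; got values such as {bad.flat[0]!r}"
        )
    if np.any((T_arr < _T_MIN) | (T_arr > _T_MAX)):
        bad = T_arr[(T_arr < _T_MIN) | (T_arr > _T_MAX)]
        raise ValueError(
            f"air temperature must lie in ({_T_MIN}, {_T_MAX}) deg C; "
            f"got values such as {bad.flat[0]!r}"
        )
    es = 0.611 * np.exp(17.502 * T_arr / (T_arr + 240.97))
    vpd = es * (1.0 - RH_arr / 100.0)
    if np.isscalar(T) and np.isscalar(RH):
        return float(vpd)
    return vpd


def interpolate_swc(
    obs,
    span: tuple | None = None,
    edge: str = "strict",
) -> pd.Series:
    """Interpolate sparse SWC observations to one value per calendar day.

    Parameters
    ----------
    obs
        A DataFrame with ``date`` and ``SWC`` (or ``swc``) columns, or an
        iterable of ``(date, value)`` pairs. Duplicate-date observations
        are averaged.
    span
        Optional ``(start, end)`` date range for the output series;
        defaults to the observation range.
    edge
        ``"strict"`` rejects spans extending beyond the first/last
        observation; ``"hold"`` extends with the nearest observed value.

    Returns
    -------
    pandas.Series
        Daily SWC indexed by normalized date, linear between bracketing
        observations and exact at observation dates. Downstream the daily
        value is held constant over all 288 grid slots of its day.
    """
    if isinstance(obs, pd.DataFrame):
        cols = {c.lower(): c for c in obs.columns}
        if "date" not in cols or "swc" not in cols:
            raise ValueError("SWC observations need 'date' and 'SWC' columns")
        pairs = list(zip(obs[cols["date"]], obs[cols["swc"]]))
    else:
        pairs = list(obs)
    if not pairs:
        raise ValueError("no SWC observations supplied")

    frame = pd.DataFrame(pairs, columns=["date", "SWC"])
    frame["date"] = pd.to_datetime(frame["date"]).dt.normalize()
    daily_obs = frame.groupby("date")["SWC"].mean().sort_index()

    if len(daily_obs) < 2 and edge != "hold":
        raise ValueError(
            "at least two SWC observations are required for interpolation "
            "(enable edge='hold' to hold a single observation constant)"
        )

    if span is None:
        start, end = daily_obs.index[0], daily_obs.index[-1]
    else:
        start = pd.Timestamp(span[0]).normalize()
        end = pd.Timestamp(span[1]).normalize()
    if edge == "strict" and (start < daily_obs.index[0] or end > daily_obs.index[-1]):
        raise ValueError(
            f"span [{start.date()}, {end.date()}] extends beyond the observation "
            f"range [{daily_obs.index[0].date()}, {daily_obs.index[-1].date()}]; "
            "enable edge='hold' to extrapolate with the nearest observation"
        )

    days = pd.date_range(start, end, freq="D")
    x = daily_obs.index.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
    y = daily_obs.to_numpy(dtype=float)
    xi = days.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
    values = np.interp(xi, x, y)  # np.interp holds edges, matching edge="hold"
    return pd.Series(values, index=days, name="SWC")


def read_logger_csv(
    path,
    columns: Mapping[str, str] | None = None,
    timestamp_col: str = "timestamp",
) -> pd.DataFrame:
    """Read a 5-minute logger CSV into a grid-aligned DataFrame.

    ``columns`` optionally maps file column names to canonical names
    (e.g. ``{"pp_kpa": "P_p"}``); when given, file columns outside the
    mapping (plus the timestamp) are rejected.
    """
    df = pd.read_csv(path)
    if timestamp_col not in df.columns:
        raise ValueError(f"{path}: missing timestamp column {timestamp_col!r}")
    parsed = pd.to_datetime(df[timestamp_col], errors="coerce")
    bad = np.flatnonzero(parsed.isna().to_numpy())
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable timestamps at file rows {rows}")
    if not parsed.is_monotonic_increasing:
        first = int(np.flatnonzero(parsed.diff().dt.total_seconds().to_numpy() < 0)[0])
        raise ValueError(f"{path}: timestamps not increasing at file row {first + 2}")
    off_grid = np.flatnonzero(
        ((parsed.dt.minute % GRID_MINUTES) != 0) | (parsed.dt.second != 0)
    )
    if off_grid.size:
        rows = ", ".join(str(i + 2) for i in off_grid[:5])
        raise ValueError(
            f"{path}: timestamps off the {GRID_MINUTES}-minute grid at file rows {rows}"
        )
    if columns is not None:
        known = set(columns) | {timestamp_col}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(f"{path}: unknown columns {unknown}")
        df = df.rename(columns=dict(columns))
    df = df.rename(columns={timestamp_col: "timestamp"})
    df["timestamp"] = parsed.values
    return df


def gap_report(df: pd.DataFrame, value_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Missing 5-minute slots between the first and last timestamp.

    Returns one row per missing slot with its timestamp and date; an empty
    frame means a complete grid. ``value_cols`` additionally counts NaN
    cells per column in the report attributes.
    """
    full = pd.date_range(df["timestamp"].min(), df["timestamp"].max(),
                         freq=f"{GRID_MINUTES}min")
    present = pd.Index(df["timestamp"])
    missing = full.difference(present)
    report = pd.DataFrame({"timestamp": missing})
    report["date"] = report["timestamp"].dt.normalize()
    report.attrs["n_expected"] = len(full)
    if value_cols:
        report.attrs["nan_counts"] = {
            c: int(df[c].isna().sum()) for c in value_cols if c in df.columns
        }
    return report


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset CSV in the canonical column order, round-trip safe."""
    ordered = [c for c in COLUMN_ORDER if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    out = df[ordered].copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    out.to_csv(path, index=False, float_format="%.6f")


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def merge_to_grid(
    meteo: pd.DataFrame,
    turgor: pd.DataFrame,
    swc_daily: pd.Series,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Inner-join meteorology, P_p and daily SWC onto the 5-minute grid.

    VPD is derived from T and RH if absent. The daily SWC value is
    broadcast to every slot of its calendar day; days without an SWC value
    (or absent from either series) are excluded and logged. Raises if the
    overlap is empty.
    """
    meteo = meteo.copy()
    if "VPD" not in meteo.columns:
        meteo["VPD"] = compute_vpd(meteo["T"], meteo["RH"])
    merged = pd.merge(meteo, turgor, on="timestamp", how="inner")
    if merged.empty:
        raise ValueError("meteorology and turgor series have no overlapping timestamps")

    dates = merged["timestamp"].dt.normalize()
    swc_map = swc_daily.copy()
    swc_map.index = pd.to_datetime(swc_map.index).normalize()
    merged["SWC"] = dates.map(swc_map)

    before = dates.nunique()
    keep = merged["SWC"].notna()
    dropped = sorted(dates[~keep].dt.date.unique())
    merged = merged.loc[keep].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no merged days remain after aligning SWC coverage")
    if dropped:
        log.info("merge_to_grid: dropped %d/%d days without SWC: %s",
                 len(dropped), before, dropped)

    if treatment is not None:
        merged["treatment"] = treatment
    elif "treatment" not in merged.columns:
        merged["treatment"] = "unspecified"

    ordered = [c for c in COLUMN_ORDER if c in merged.columns]
    ordered += [c for c in merged.columns if c not in ordered]
    return merged[ordered]
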