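"""Diurnal P_p curve classification: State I vs State II (N/M/V).

A day's leaf-turgor proxy curve (probe output pressure P_p, 288 samples)
is either unimodal with a midday maximum (State I, no or mild water
stress) or troughed with a pronounced daytime minimum (State II, severe
stress, appearing as 'N', 'M' or 'V' shapes). Classification is a
two-step rule:

1. Rate rule - the mean P_p rise rate over 05:00-10:00 and the mean fall
   rate over 15:00-20:00 (fall rate positive when P_p declines). Both
   negative -> 'V'; exactly one negative -> 'N'; both positive ->
   provisionally State I.
2. Extrema screen - the daytime segment is smoothed and its prominent
   local maxima counted; two or more maxima separated by a deep trough
   override the provisional State I to 'M'. This makes the manual
   graph-screening step deterministic and reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import (
    SLOTS_PER_DAY,
    GRID_MINUTES,
    ClassifierPolicy,
    GapPolicy,
    SegmentPolicy,
)

log = logging.getLogger(__name__)

_HOURS = np.arange(SLOTS_PER_DAY) * GRID_MINUTES / 60.0


@dataclass
class DailyCurve:
    """One calendar day of P_p on the 5-minute grid (NaN = missing slot)."""

    date: pd.Timestamp
    values: np.ndarray
    treatment: str = "unspecified"
    completeness: float = 1.0

    @property
    def hours(self) -> np.ndarray:
        return _HOURS

    def range(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(finite.max() - finite.min()) if finite.size else float("nan")


@dataclass
class DayLabel:
    """Classification outcome for one day."""

    date: pd.Timestamp
    state: str | None  # "I", "II", or None if unclassifiable
    subtype: str  # "none", "N", "M", "V"
    rise_rate: float = float("nan")
    fall_rate: float = float("nan")
    extrema_count: int = 0
    screened: bool = False
    classifiable: bool = True
    flags: list[str] = field(default_factory=list)
    treatment: str = "unspecified"


@dataclass
class DailySummary:
    ppmax: float
    ppmax_time: time
    ppmin: float
    ppmin_time: time
    mean: float


def _slot_range(window: tuple[float, float]) -> slice:
    start = int(round(window[0] * 60 / GRID_MINUTES))
    stop = int(round(window[1] * 60 / GRID_MINUTES))
    return slice(start, stop)


def extract_daily_curves(
    series: pd.DataFrame,
    gap_policy: GapPolicy = GapPolicy(),
    classifier_policy: ClassifierPolicy = ClassifierPolicy(),
) -> tuple[list[DailyCurve], list[tuple[object, str]]]:
    """Split a grid-aligned series into daily curves, applying the gap policy.

    Days whose rate windows, daytime segment, or full day miss more than
    the policy fraction of slots are excluded (returned in the exclusion
    report); remaining small gaps are filled linearly. An empty series
    yields an empty list.
    """
    if series.empty:
        return [], []
    windows = {
        "rise window": _slot_range(classifier_policy.rise_window),
        "fall window": _slot_range(classifier_policy.fall_window),
        "daytime segment": _slot_range(classifier_policy.daytime),
        "whole day": slice(0, SLOTS_PER_DAY),
    }
    curves: list[DailyCurve] = []
    excluded: list[tuple[object, str]] = []
    ts = pd.to_datetime(series["timestamp"])
    slot = (ts.dt.hour * 60 + ts.dt.minute) // GRID_MINUTES
    for date, group in series.groupby(ts.dt.normalize()):
        values = np.full(SLOTS_PER_DAY, np.nan)
        values[slot.loc[group.index].to_numpy()] = group["P_p"].to_numpy(dtype=float)
        completeness = float(np.isfinite(values).mean())
        reason = None
        for name, sl in windows.items():
            frac_missing = float(np.isnan(values[sl]).mean())
            if frac_missing > gap_policy.max_missing_frac:
                reason = f"{name} missing {frac_missing:.1%} of slots"
                break
        if reason is not None:
            excluded.append((date.date(), reason))
            continue
        if np.isnan(values).any():
            filled = pd.Series(values).interpolate(
                method="linear", limit_direction="both"
            )
            values = filled.to_numpy()
        treatment = (
            str(group["treatment"].iloc[0]) if "treatment" in group else "unspecified"
        )
        curves.append(DailyCurve(date, values, treatment, completeness))
    if excluded:
        log.info("extract_daily_curves: excluded %d days: %s", len(excluded), excluded)
    return curves, excluded


def window_rates(
    curve: DailyCurve, policy: ClassifierPolicy = ClassifierPolicy()
) -> tuple[float, float]:
    """Mean P_p rise rate (05:00-10:00) and fall rate (15:00-20:00), kPa/h.

    The rate is the least-squares slope of P_p against clock time over the
    half-open window (or the endpoint difference if the policy says so).
    The fall rate is the negated slope, so a unimodal State-I day yields
    two positive rates. NaN slots in a window make the day unclassifiable.
    """

    def rate(window: tuple[float, float]) -> float:
        sl = _slot_range(window)
        y = curve.values[sl]
        if not np.all(np.isfinite(y)):
            raise ValueError(
                f"{curve.date.date()}: window {window} incomplete; day unclassifiable"
            )
        x = curve.hours[sl]
        if policy.rate_method == "endpoint":
            return float((y[-1] - y[0]) / (x[-1] - x[0]))
        if policy.rate_method != "slope":
            raise ValueError(f"unknown rate_method {policy.rate_method!r}")
        return float(np.polyfit(x, y, 1)[0])

    rise = rate(policy.rise_window)
    fall = -rate(policy.fall_window)
    return rise, fall


def _smooth(values: np.ndarray, smooth_minutes: int) -> np.ndarray:
    window = max(1, int(round(smooth_minutes / GRID_MINUTES)))
    if window % 2 == 0:
        window += 1
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def classify_day(
    curve: DailyCurve, policy: ClassifierPolicy = ClassifierPolicy()
) -> DayLabel:
    """Classify one daily curve into State I or State II (N/M/V).

    Rate rule first; provisional State-I days then pass through the
    extrema screen (smoothed daytime maxima with prominence above a
    fraction of the daily range), which can override to 'M'. A rate of
    exactly zero is resolved by the tie policy (counts as positive by
    default) and flagged. Deterministic given curve and policy, and
    invariant to adding a constant to the whole curve.
    """
    label = DayLabel(date=curve.date, state=None, subtype="none",
                     treatment=curve.treatment)
    try:
        rise, fall = window_rates(curve, policy)
    except ValueError as exc:
        label.classifiable = False
        label.flags.append(str(exc))
        return label
    label.rise_rate, label.fall_rate = rise, fall

    def is_negative(rate: float) -> bool:
        if abs(rate) < 1e-12:  # numerically zero slope -> tie policy
            label.flags.append("tie_rate_zero")
            return not policy.tie_positive
        return rate < 0.0

    neg = sum(is_negative(r) for r in (rise, fall))
    if neg == 2:
        label.state, label.subtype = "II", "V"
        return label
    if neg == 1:
        label.state, label.subtype = "II", "N"
        return label

    # Provisional State I: run the extrema screen on the daytime segment.
    sl = _slot_range(policy.daytime)
    segment = _smooth(curve.values, policy.smooth_minutes)[sl]
    prominence = policy.prominence_frac * curve.range()
    if prominence > 0:
        peaks, _ = find_peaks(segment, prominence=prominence)
    else:
        peaks = np.array([], dtype=int)
        label.flags.append("degenerate_flat_curve")
    label.extrema_count = int(len(peaks))
    if len(peaks) >= 2:
        label.state, label.subtype, label.screened = "II", "M", True
    else:
        label.state, label.subtype = "I", "none"
    return label


def daily_summary(curve: DailyCurve) -> DailySummary:
    """Daily P_p maximum/minimum with clock times (earliest tie wins) and mean."""
    values = curve.values
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError(f"{curve.date.date()}: no finite samples")
    vmax = np.nanmax(values)
    vmin = np.nanmin(values)
    imax = int(np.flatnonzero(finite & (values == vmax))[0])
    imin = int(np.flatnonzero(finite & (values == vmin))[0])

    def slot_time(i: int) -> time:
        minutes = i * GRID_MINUTES
        return time(minutes // 60, minutes % 60)

    return DailySummary(
        ppmax=float(vmax),
        ppmax_time=slot_time(imax),
        ppmin=float(vmin),
        ppmin_time=slot_time(imin),
        mean=float(np.nanmean(values)),
    )


def segment_state1_stages(
    curve: DailyCurve,
    label: DayLabel,
    policy: SegmentPolicy = SegmentPolicy(),
    classifier_policy: ClassifierPolicy = ClassifierPolicy(),
) -> dict[str, tuple[int, int]]:
    """Partition a State-I day into its four sequential stages.

    Returns slot intervals (half-open) for the valley fluctuation, rapid
    rising, peak fluctuation and decay stages. The valley ends where the
    smoothed derivative first exceeds +eps (kPa/h); the rise ends where
    the smoothed curve first enters the peak band (within ``delta_frac``
    of the daily range below the smoothed maximum); the peak stage lasts
    while the curve stays in that band. The intervals are contiguous and
    cover the full day.
    """
    if label.state != "I":
        raise ValueError(f"{curve.date.date()}: stage segmentation requires State I")
    rng = curve.range()
    if not np.isfinite(rng) or rng == 0.0 or "tie_rate_zero" in label.flags:
        raise ValueError(
            f"{curve.date.date()}: degenerate (flat) curve cannot be segmented"
        )
    sm = _smooth(curve.values, classifier_policy.smooth_minutes)
    deriv = np.gradient(sm, _HOURS)  # kPa/h
    above = np.flatnonzero(deriv > policy.eps)
    t_a = int(above[0]) if above.size else SLOTS_PER_DAY
    band_lo = sm.max() - policy.delta_frac * (sm.max() - sm.min())
    in_band = np.flatnonzero(sm[t_a:] >= band_lo)
    t_b = int(t_a + in_band[0]) if in_band.size else SLOTS_PER_DAY
    out_band = np.flatnonzero(sm[t_b:] < band_lo)
    t_c = int(t_b + out_band[0]) if out_band.size else SLOTS_PER_DAY
    return {
        "valley_fluctuation": (0, t_a),
        "rapid_rising": (t_a, t_b),
        "peak_fluctuation": (t_b, t_c),
        "decay": (t_c, SLOTS_PER_DAY),
    }


def label_days(
    curves: list[DailyCurve], policy: ClassifierPolicy = ClassifierPolicy()
) -> pd.DataFrame:
    """Classify and summarize a list of daily curves into one table.

    Columns: date, treatment, state, subtype, rise_rate, fall_rate,
    ppmax, ppmax_time, ppmin, ppmin_time, screened, classifiable - the
    per-day label CSV of the pipeline.
    """
    rows = []
    for curve in curves:
        lab = classify_day(curve, policy)
        summary = daily_summary(curve) if np.isfinite(curve.values).any() else None
        rows.append(
            {
                "date": pd.Timestamp(curve.date).normalize(),
                "treatment": curve.treatment,
                "state": lab.state,
                "subtype": lab.subtype,
                "rise_rate": lab.rise_rate,
                "fall_rate": lab.fall_rate,
                "ppmax": summary.ppmax if summary else float("nan"),
                "ppmax_time": summary.ppmax_time.isoformat(timespec="minutes")
                if summary
                else "",
                "ppmin": summary.ppmin if summary else float("nan"),
                "ppmin_time": summary.ppmin_time.isoformat(timespec="minutes")
                if summary
                else "",
                "screened": lab.screened,
                "classifiable": lab.classifiable,
            }
        )
    return pd.DataFrame(rows)
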