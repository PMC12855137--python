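"""Soil-water stress thresholds and per-state environmental correlations.

Combining each day's diurnal-state label with that day's soil water
content yields two operational irrigation thresholds per crop: an upper
bound U (the highest SWC at which a stressed, State-II day was still
observed) and a lower bound L (the lowest SWC at which an unstressed,
State-I day was still observed). Above U only State I occurs; below L
only State II; [L, U] is the ambiguous band where both appear. The
estimator is the empirical support boundary (max over State-II days /
min over State-I days); integer rounding is a reporting option only.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ALL_FACTORS

log = logging.getLogger(__name__)


@dataclass
class ThresholdReport:
    crop: str
    U: float | None  # SWC % above which only State I was observed
    L: float | None  # SWC % below which only State II was observed
    band: tuple[float, float] | None
    state_means: dict[str, float]
    day_counts: dict[str, int]
    U_rounded: int | None = None
    L_rounded: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "crop": self.crop,
            "U": self.U,
            "L": self.L,
            "band": list(self.band) if self.band else None,
            "state_means": self.state_means,
            "day_counts": self.day_counts,
            "U_rounded": self.U_rounded,
            "L_rounded": self.L_rounded,
            "warnings": self.warnings,
        }


def _swc_by_state(day_labels: pd.DataFrame, daily_swc) -> pd.DataFrame:
    labels = day_labels.loc[day_labels["state"].isin(["I", "II"])].copy()
    swc = pd.Series(daily_swc).copy()
    swc.index = pd.to_datetime(swc.index).normalize()
    labels["date"] = pd.to_datetime(labels["date"]).dt.normalize()
    labels["SWC"] = labels["date"].map(swc)
    missing = labels["SWC"].isna()
    if missing.any():
        raise ValueError(
            f"no SWC available for labeled days: "
            f"{sorted(labels.loc[missing, 'date'].dt.date.unique())[:5]}"
        )
    return labels


def derive_thresholds(
    day_labels: pd.DataFrame,
    daily_swc,
    crop: str = "unspecified",
    rounding: bool = False,
) -> ThresholdReport:
    """Empirical SWC stress thresholds from labeled days.

    U = max SWC over State-II days; L = min SWC over State-I days. A state
    with no days leaves its bound undefined (with a warning, not an
    error). ``rounding`` adds integer-rounded bounds for reporting; the
    continuous values are always kept.
    """
    labels = _swc_by_state(day_labels, daily_swc)
    report = ThresholdReport(
        crop=crop,
        U=None,
        L=None,
        band=None,
        state_means={
            state: float(g["SWC"].mean()) for state, g in labels.groupby("state")
        },
        day_counts={state: int(len(g)) for state, g in labels.groupby("state")},
    )
    state2 = labels.loc[labels["state"] == "II", "SWC"]
    state1 = labels.loc[labels["state"] == "I", "SWC"]
    if len(state2):
        report.U = float(state2.max())
    else:
        msg = "no State-II days: upper threshold U undefined"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    if len(state1):
        report.L = float(state1.min())
    else:
        msg = "no State-I days: lower threshold L undefined"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    if report.U is not None and report.L is not None:
        report.band = (report.L, report.U)
    if rounding:
        report.U_rounded = int(round(report.U)) if report.U is not None else None
        report.L_rounded = int(round(report.L)) if report.L is not None else None
    return report


def state_swc_means(day_labels: pd.DataFrame, daily_swc) -> dict[str, float]:
    """Arithmetic mean SWC per diurnal state."""
    labels = _swc_by_state(day_labels, daily_swc)
    return {state: float(g["SWC"].mean()) for state, g in labels.groupby("state")}


def correlate(
    dataset: pd.DataFrame,
    day_labels: pd.DataFrame | None = None,
    scope: str = "whole",
    alpha: float = 0.05,
    daily: bool = False,
    factors=ALL_FACTORS,
) -> pd.DataFrame:
    """Pearson correlation of P_p with each environmental factor.

    ``scope`` restricts the instantaneous 5-minute samples to days
    labeled State I or II (``"whole"`` uses all labeled-or-not rows).
    ``daily=True`` correlates daily means instead. Two-sided significance
    at ``alpha`` uses the t-distribution transform of r. Zero-variance
    columns yield an undefined (NaN) coefficient, flagged in the
    ``defined`` column.
    """
    df = dataset.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    if scope in ("I", "II"):
        if day_labels is None:
            raise ValueError("state-scoped correlation requires day labels")
        labels = day_labels.copy()
        labels["date"] = pd.to_datetime(labels["date"]).dt.normalize()
        days = set(labels.loc[labels["state"] == scope, "date"])
        df = df.loc[df["date"].isin(days)]
    elif scope != "whole":
        raise ValueError(f"unknown scope {scope!r}; expected 'whole', 'I' or 'II'")
    if daily:
        df = df.groupby("date", as_index=False).mean(numeric_only=True)
    if len(df) < 30:
        raise ValueError(f"scope {scope!r} has {len(df)} samples; at least 30 required")

    rows = []
    y = df["P_p"].to_numpy(dtype=float)
    for factor in factors:
        x = df[factor].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            log.warning("correlate: zero variance for %s in scope %s", factor, scope)
            rows.append(
                {"factor": factor, "r": np.nan, "p": np.nan,
                 "significant": False, "defined": False, "n": len(df)}
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"factor": factor, "r": float(r), "p": float(p),
             "significant": bool(p < alpha), "defined": True, "n": len(df)}
        )
    out = pd.DataFrame(rows).set_index("factor")
    out.attrs["scope"] = scope
    return out


def correlation_matrix(
    dataset: pd.DataFrame,
    day_labels: pd.DataFrame | None = None,
    scope: str = "whole",
    factors=ALL_FACTORS,
) -> pd.DataFrame:
    """Full symmetric Pearson matrix over P_p and the factors."""
    df = dataset.copy()
    if scope in ("I", "II"):
        if day_labels is None:
            raise ValueError("state-scoped correlation requires day labels")
        labels = day_labels.copy()
        labels["date"] = pd.to_datetime(labels["date"]).dt.normalize()
        days = set(labels.loc[labels["state"] == scope, "date"])
        dates = pd.to_datetime(df["timestamp"]).dt.normalize()
        df = df.loc[dates.isin(days)]
    cols = ["P_p", *factors]
    return df[cols].corr(method="pearson")
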