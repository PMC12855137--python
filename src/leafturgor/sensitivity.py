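"""What-if soil-water scenarios: predict P_p under hypothetical SWC shifts.

With a fitted predictor whose inputs include soil water content, the SWC
column is shifted by a few percentage points (irrigating more or less
than observed, everything else held fixed), the full P_p series is
re-predicted, and the change in the predicted daily extrema is reported
per diurnal state. Because P_p falls as the soil wets, a +5-point shift
should lower the predicted State-I daily maximum and a -5-point shift
raise it; the response quantifies how much headroom an irrigation (or a
skipped one) buys.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import TurgorPredictor, build_feature_table

log = logging.getLogger(__name__)


def perturb_swc(
    dataset: pd.DataFrame,
    delta: float,
    mode: str = "absolute",
    theta_f: float | None = None,
) -> pd.DataFrame:
    """Shift the SWC column; everything else untouched. Pure (returns a copy).

    ``mode="absolute"`` adds ``delta`` percentage points of volumetric
    SWC (the default reading of "increased or decreased by 5%");
    ``mode="relative"`` multiplies by ``1 + delta/100``. Values are
    clipped to (0, theta_f] when a field capacity is given; clip events
    are logged and a fully clipped column raises a warning.
    """
    if "SWC" not in dataset.columns:
        raise ValueError("dataset has no SWC column to perturb")
    out = dataset.copy()
    if mode == "absolute":
        shifted = out["SWC"].to_numpy(dtype=float) + delta
    elif mode == "relative":
        shifted = out["SWC"].to_numpy(dtype=float) * (1.0 + delta / 100.0)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'absolute' or 'relative'")
    upper = theta_f if theta_f is not None else np.inf
    clipped = np.clip(shifted, np.nextafter(0.0, 1.0), upper)
    n_clip = int(np.sum(clipped != shifted))
    if n_clip:
        log.info("perturb_swc(delta=%s): clipped %d of %d values", delta, n_clip,
                 len(clipped))
    if n_clip == len(clipped) and delta != 0:
        warnings.warn(
            f"perturb_swc: every SWC value was clipped (delta={delta}); the "
            "scenario degenerates to the clip bound",
            stacklevel=2,
        )
    out["SWC"] = clipped
    return out


@dataclass
class ScenarioResult:
    """Per-state response of the predicted daily extrema to one SWC shift."""

    delta: float
    per_state: dict[str, dict] = field(default_factory=dict)
    note: str = ""


def _daily_extrema(table: pd.DataFrame, predicted: np.ndarray) -> pd.DataFrame:
    frame = table[["date", "state"]].copy()
    frame["pred"] = predicted
    grouped = frame.groupby(["date", "state"])["pred"].agg(["max", "min"])
    return grouped.reset_index().rename(columns={"max": "ppmax", "min": "ppmin"})


def scenario_response(
    predictor: TurgorPredictor,
    dataset: pd.DataFrame,
    day_labels: pd.DataFrame,
    deltas=(-5.0, 5.0),
    mode: str = "absolute",
    theta_f: float | None = None,
) -> list[ScenarioResult]:
    """Predicted daily P_p extrema under each SWC shift, against baseline.

    The baseline is the predictor's own prediction at observed SWC (never
    the measured values), so each delta isolates the modeled soil-water
    response. State attribution of shifted predictions keeps the baseline
    day labels. The input dataset is never mutated. Requires a predictor
    trained on a combination that includes SWC.
    """
    if "SWC" not in predictor.spec.inputs:
        raise ValueError(
            "scenario undefined: the predictor was trained without SWC "
            f"(combination {predictor.spec.id} inputs {predictor.spec.inputs})"
        )
    base_table = build_feature_table(dataset, day_labels, predictor.spec)
    base_pred = predictor.predict(base_table)
    base_extrema = _daily_extrema(base_table, base_pred)

    results = []
    for delta in deltas:
        shifted = perturb_swc(dataset, delta, mode=mode, theta_f=theta_f)
        table = build_feature_table(shifted, day_labels, predictor.spec)
        pred = predictor.predict(table)
        extrema = _daily_extrema(table, pred)
        merged = base_extrema.merge(
            extrema, on=["date", "state"], suffixes=("_base", "_shift")
        )
        result = ScenarioResult(delta=float(delta))
        for state, group in merged.groupby("state"):
            result.per_state[str(state)] = {
                "baseline_ppmax": float(group["ppmax_base"].mean()),
                "shifted_ppmax": float(group["ppmax_shift"].mean()),
                "delta_ppmax": float(
                    (group["ppmax_shift"] - group["ppmax_base"]).mean()
                ),
                "baseline_ppmin": float(group["ppmin_base"].mean()),
                "shifted_ppmin": float(group["ppmin_shift"].mean()),
                "delta_ppmin": float(
                    (group["ppmin_shift"] - group["ppmin_base"]).mean()
                ),
                "n_days": int(len(group)),
            }
        d1 = result.per_state.get("I", {}).get("delta_ppmax")
        if d1 is not None and delta != 0:
            direction = "falls" if d1 < 0 else "rises"
            result.note = (
                f"State-I predicted daily maximum {direction} by "
                f"{abs(d1):.2f} kPa under a {delta:+g}-point SWC shift"
            )
        results.append(result)
    return results


def response_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Flatten scenario results into one row per (delta, state)."""
    rows = []
    for res in results:
        for state, vals in res.per_state.items():
            rows.append({"delta": res.delta, "state": state, **vals})
    return pd.DataFrame(rows)
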