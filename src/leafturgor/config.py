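"""Shared conventions and policies for the leaf-turgor pipeline.

Everything here is plain data: the 5-minute sampling grid, the canonical
column order of merged datasets, and the small policy dataclasses that the
processing stages consume. Policies are frozen so a run's configuration can
be hashed into its manifest.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

#: Logger cadence in minutes; every daily curve has 288 slots.
GRID_MINUTES = 5
SLOTS_PER_DAY = 24 * 60 // GRID_MINUTES

#: Fixed column order of merged dataset CSVs.
COLUMN_ORDER = ["timestamp", "Rs", "T", "RH", "WS", "VPD", "SWC", "P_p", "treatment"]

#: Meteorological driver columns (model inputs without soil water).
METEO_FACTORS = ("Rs", "T", "RH", "WS", "VPD")
#: All candidate environmental drivers of P_p.
ALL_FACTORS = METEO_FACTORS + ("SWC",)


@dataclass(frozen=True)
class GapPolicy:
    """How missing 5-minute slots are handled before classification.

    Days whose rate windows (or the day as a whole) miss more than
    ``max_missing_frac`` of their slots are excluded from classification;
    smaller gaps are filled linearly.
    """

    max_missing_frac: float = 0.05
    fill: str = "linear"


@dataclass(frozen=True)
class ClassifierPolicy:
    """Rate-rule and extrema-screen settings for diurnal state classification.

    The rise window and fall window are clock-hour half-open intervals over
    which the mean P_p rise/fall rate is measured. ``rate_method`` selects
    the least-squares slope (default) or the endpoint difference. The
    extrema screen smooths the daytime segment with a centred moving
    average and counts local maxima whose prominence exceeds
    ``prominence_frac`` of the day's P_p range.
    """

    rate_method: str = "slope"  # {"slope", "endpoint"}
    rise_window: tuple[float, float] = (5.0, 10.0)
    fall_window: tuple[float, float] = (15.0, 20.0)
    daytime: tuple[float, float] = (6.0, 20.0)
    smooth_minutes: int = 35
    prominence_frac: float = 0.10
    tie_positive: bool = True


@dataclass(frozen=True)
class SegmentPolicy:
    """Stage-segmentation thresholds for unimodal (State I) days.

    ``eps`` is the smoothed-derivative threshold (kPa/h) that ends the
    valley-fluctuation stage; ``delta_frac`` sets the peak band as a
    fraction of the daily range below the smoothed maximum.
    """

    eps: float = 0.5
    delta_frac: float = 0.05


def default_config() -> dict:
    """All pipeline defaults as one plain dictionary."""
    return {
        "gap_policy": dataclasses.asdict(GapPolicy()),
        "classifier_policy": dataclasses.asdict(ClassifierPolicy()),
        "segment_policy": dataclasses.asdict(SegmentPolicy()),
        "columns": {name: name for name in COLUMN_ORDER},
    }


def load_config(path) -> dict:
    """Read a YAML key-value config file and overlay it on the defaults."""
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def policies_from_config(cfg: dict):
    """Build the three policy objects from a config dictionary."""
    gp = GapPolicy(**{k: v for k, v in cfg.get("gap_policy", {}).items()})
    cp_raw = dict(cfg.get("classifier_policy", {}))
    for key in ("rise_window", "fall_window", "daytime"):
        if key in cp_raw:
            cp_raw[key] = tuple(cp_raw[key])
    cp = ClassifierPolicy(**cp_raw)
    sp = SegmentPolicy(**{k: v for k, v in cfg.get("segment_policy", {}).items()})
    return gp, cp, sp
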