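"""Synthetic greenhouse seasons: meteorology, soil water and P_p curves.

The generator emulates the statistical structure the diagnosis pipeline
assumes, so every stage is testable without field data:

* greenhouse meteorology on the 5-minute grid - daylight half-sine net
  radiation with day-to-day amplitude jitter and occasional overcast
  days; air temperature lagging radiation; relative humidity anti-phase
  with temperature; light wind strongest at night; VPD always derived
  from T and RH with the same formula the ingest stage uses;
* irrigation-driven soil water content - exponential drawdown between
  irrigation events, step increases at events, capped at field capacity;
* state-conditional diurnal P_p templates - a four-stage unimodal curve
  for State I and flattened, elevated troughed curves for the State-II
  'N'/'M'/'V' subtypes, with the curve level rising steeply as the soil
  dries (the probe output drifts upward over a drying cycle) and the
  amplitude tracking that day's radiation;
* ground-truth labels emitted alongside the data, never consumed by the
  pipeline under test.

Day states follow the planted SWC bounds: above U* only State I, below
L* only State II, a Bernoulli draw in between. Fixed benchmark scenarios
instead carry explicit state plans with state-consistent SWC, so their
State-I percentages are exact by construction.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import ingest
from .config import COLUMN_ORDER, GRID_MINUTES, SLOTS_PER_DAY

_HOURS = np.arange(SLOTS_PER_DAY) * GRID_MINUTES / 60.0

#: State-II subtype frequencies as printed for the observed stressed days,
#: renormalised to sum to one (the printed triple sums to 102.06%).
SUBTYPE_WEIGHTS = {"N": 36.08 / 102.06, "M": 30.93 / 102.06, "V": 35.05 / 102.06}


@dataclass(frozen=True)
class CropProfile:
    """Per-crop constants of the generator and the diagnosis rules.

    ``upper_bound``/``lower_bound`` are the planted SWC state-switching
    thresholds (U*, L*): the generator plants only State I above U* and
    only State II below L*. ``night_base`` and ``amplitude`` are the
    State-I template level and peak height (kPa) of an unstressed,
    fully irrigated day; the level is multiplied by
    ``1 + level_coef * s`` where s = (theta_f - SWC)/(theta_f - L*) is
    the normalised soil-drying stress (0 at field capacity, 1 at L*),
    continued below L* with slope ``state2_level_slope`` - the probe
    signal saturates once turgor has collapsed. State-II curves are
    flattened by ``state2_amp_factor``. Deficit treatments additionally
    scale the daily minimum (curve level) and maximum (curve amplitude).
    """

    crop: str
    theta_f: float  # field capacity, vol %
    upper_bound: float  # U*: SWC above which only State I is planted
    lower_bound: float  # L*: SWC below which only State II is planted
    night_base: float = 20.0  # kPa, unstressed State-I nocturnal level
    amplitude: float = 40.0  # kPa, unstressed full-irrigation peak height
    level_coef: float = 7.0  # stress multiplier on the curve level
    amp_level_coef: float = 0.5  # stress multiplier on the amplitude
    state2_amp_factor: float = 0.35  # State-II curves are flattened
    state2_level_slope: float = 0.3  # saturated level response in State II
    rs_amp: float = 700.0  # W/m2, nominal clear-day radiation peak
    day_start: float = 6.0  # clock hours of the daylight window
    day_end: float = 19.0
    t_mean: float = 26.0  # deg C, seasonal mean air temperature
    t_amp: float = 7.0  # deg C, diurnal half-range
    rh_mean: float = 65.0  # %, seasonal mean relative humidity
    rh_amp: float = 20.0  # %, diurnal half-range (anti-phase with T)
    sweep_range: tuple[float, float] = (14.0, 26.0)  # drawdown span, vol %
    subtype_weights: tuple[float, float, float] = (
        SUBTYPE_WEIGHTS["N"],
        SUBTYPE_WEIGHTS["M"],
        SUBTYPE_WEIGHTS["V"],
    )
    #: treatment -> (max_scale, min_scale): deficit irrigation elevates the
    #: daily P_p maximum and minimum relative to full irrigation.
    treatment_scales: tuple = (("TB", (1.0, 1.0)), ("T0", (1.3, 1.5)))

    def scales(self, treatment: str) -> tuple[float, float]:
        table = dict(self.treatment_scales)
        return table.get(treatment, (1.0, 1.0))

    def stress(self, swc, state: str = "I") -> np.ndarray:
        """Normalised drying stress driving the curve level.

        s = (theta_f - SWC)/(theta_f - L*): 0 at field capacity, 1 at the
        lower state bound. On State-II days the probe signal reflects bulk
        internal gas changes rather than fine turgor variation, so the
        level response saturates: the slope around s = 1 flattens to
        ``state2_level_slope``.
        """
        s = (self.theta_f - np.asarray(swc, dtype=float)) / (
            self.theta_f - self.lower_bound
        )
        if state == "II":
            s = 1.0 + self.state2_level_slope * (s - 1.0)
        return np.clip(s, 0.0, None)


TOMATO = CropProfile(
    crop="tomato",
    theta_f=32.0,
    upper_bound=20.0,
    lower_bound=18.0,
    rs_amp=700.0,
    t_mean=26.0,
    t_amp=7.0,
    rh_mean=62.0,
    rh_amp=20.0,
    sweep_range=(14.0, 26.0),
    treatment_scales=(("TB", (1.0, 1.0)), ("T0", (1.3, 1.5))),
)

CELERY = CropProfile(
    crop="celery",
    theta_f=38.0,
    upper_bound=19.0,
    lower_bound=16.0,
    rs_amp=350.0,
    day_start=6.5,
    day_end=18.5,
    t_mean=14.0,
    t_amp=5.0,
    rh_mean=75.0,
    rh_amp=15.0,
    sweep_range=(12.0, 24.0),
    treatment_scales=(("CFI", (1.0, 1.0)), ("CDI", (1.3, 1.38))),
)

PROFILES = {"tomato": TOMATO, "celery": CELERY}


@dataclass
class SeasonConfig:
    """One simulated season. The seed fixes every random draw."""

    profile: CropProfile = TOMATO
    treatment: str = "TB"
    n_days: int = 65
    start: str = "2021-07-01"
    seed: int = 0
    sigma: float = 0.003  # additive noise s.d. as a fraction of daily range
    irrigation_days: tuple = ()  # day indices of irrigation events
    irrigation_depths: tuple = ()  # mm per event
    swc0: float | None = None
    state_plan: tuple | None = None  # per-day "I"/"II" plan (overrides SWC rule)
    swc_override: tuple | None = None  # explicit daily SWC values
    p_state1_band: float = 0.5  # P(State I) inside the ambiguous band
    subtype_mode: str = "by_depth"  # {"by_depth", "mixture"}
    scenario: str | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["profile"] = dataclasses.asdict(self.profile)
        return out


# --- diurnal P_p templates: (clock hour, fraction of the day's amplitude) ---
# State I follows the four sequential stages (valley fluctuation, rapid
# rise, peak fluctuation, decay); the State-II shapes put the pronounced
# minimum in daytime ('V'), a declining day with an afternoon shoulder
# ('N'), or twin daytime peaks around a midday trough ('M').
_TEMPLATES: dict[str, tuple[tuple[float, float], ...]] = {
    "I": (
        (0.0, 0.05), (4.5, 0.02), (6.0, 0.02), (8.0, 0.35), (10.5, 0.90),
        (12.0, 1.00), (13.2, 1.00), (14.5, 0.95), (16.0, 0.80), (18.0, 0.50),
        (20.0, 0.22), (22.0, 0.10), (23.9167, 0.06),
    ),
    "V": (
        (0.0, 0.95), (2.0, 1.00), (4.0, 0.98), (5.0, 0.95), (7.0, 0.70),
        (10.0, 0.30), (11.5, 0.12), (13.0, 0.10), (14.5, 0.15), (17.0, 0.45),
        (20.0, 0.80), (22.0, 0.95), (23.9167, 0.95),
    ),
    "N": (
        (0.0, 1.00), (3.0, 0.95), (5.0, 0.85), (8.0, 0.50), (10.0, 0.30),
        (12.0, 0.20), (13.5, 0.35), (15.0, 0.42), (17.0, 0.30), (20.0, 0.12),
        (22.0, 0.30), (23.9167, 0.60),
    ),
    "M": (
        (0.0, 0.08), (5.0, 0.05), (7.0, 0.35), (9.0, 0.80), (10.5, 0.95),
        (12.0, 0.45), (13.0, 0.40), (14.2, 0.55), (16.0, 1.00), (17.5, 0.75),
        (20.0, 0.22), (22.0, 0.12), (23.9167, 0.08),
    ),
}


@lru_cache(maxsize=None)
def _template_curve(key: str) -> np.ndarray:
    knots = np.array(_TEMPLATES[key])
    return PchipInterpolator(knots[:, 0], knots[:, 1])(_HOURS)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_meteorology(config: SeasonConfig) -> pd.DataFrame:
    """Greenhouse meteorology on the 5-minute grid.

    Net radiation is a daylight half-sine (exactly zero at night) whose
    peak jitters day to day, with occasional overcast days at a quarter
    to half amplitude. Temperature is a diurnal sinusoid peaking ~1.5 h
    after the radiation peak, humidity runs anti-phase with temperature
    (bounded [20, 100] %), wind is a small positive flow that is calmest
    around midday, and VPD is always derived from T and RH - never drawn
    independently.
    """
    (rng,) = _rng_streams(config.seed, 1)
    profile = config.profile
    index = pd.date_range(
        config.start, periods=config.n_days * SLOTS_PER_DAY, freq=f"{GRID_MINUTES}min"
    )
    h = np.tile(_HOURS, config.n_days)

    amp = rng.normal(1.0, 0.12, size=config.n_days).clip(0.5, 1.3)
    overcast = rng.random(config.n_days) < 0.15
    amp[overcast] *= rng.uniform(0.25, 0.5, size=int(overcast.sum()))
    amp_slots = np.repeat(amp, SLOTS_PER_DAY)

    span = profile.day_end - profile.day_start
    daylight = (h >= profile.day_start) & (h <= profile.day_end)
    rs = np.zeros_like(h)
    rs[daylight] = (
        amp_slots[daylight]
        * profile.rs_amp
        * np.sin(np.pi * (h[daylight] - profile.day_start) / span)
    )
    rs = np.maximum(rs, 0.0)  # sin(pi) underflows slightly negative at dusk

    t_day = profile.t_mean + 4.0 * (amp - 0.9)
    T = (
        np.repeat(t_day, SLOTS_PER_DAY)
        + profile.t_amp * np.cos(2 * np.pi * (h - 14.5) / 24.0)
        + rng.normal(0.0, 0.05, size=h.size)
    )
    rh_day = profile.rh_mean - 10.0 * (amp - 0.9)
    RH = np.clip(
        np.repeat(rh_day, SLOTS_PER_DAY)
        - profile.rh_amp * np.cos(2 * np.pi * (h - 14.5) / 24.0)
        + rng.normal(0.0, 0.3, size=h.size),
        20.0,
        100.0,
    )
    WS = np.clip(
        0.25
        - 0.20 * np.cos(2 * np.pi * (h - 13.0) / 24.0)
        + rng.normal(0.0, 0.05, size=h.size),
        0.0,
        None,
    )
    return pd.DataFrame(
        {
            "timestamp": index,
            "Rs": rs,
            "T": T,
            "RH": RH,
            "WS": WS,
            "VPD": ingest.compute_vpd(T, RH),
        }
    )


def simulate_swc(config: SeasonConfig) -> pd.Series:
    """Daily soil water content for the season.

    An explicit ``swc_override`` wins; a ``state_plan`` produces
    state-consistent SWC (State-I runs drawing down above U*, State-II
    runs below L*, reset at run starts as if irrigated); otherwise SWC
    decays exponentially between irrigation events and steps up at each
    event in proportion to its depth, capped at field capacity. With no
    schedule, a default 25-day irrigation cycle spans the profile's
    characteristic drawdown range.
    """
    profile = config.profile
    days = pd.date_range(config.start, periods=config.n_days, freq="D")
    _, rng = _rng_streams(config.seed, 2)

    if config.swc_override is not None:
        values = np.asarray(config.swc_override, dtype=float)
        if values.size != config.n_days:
            raise ValueError("swc_override length must equal n_days")
        if np.any(values > profile.theta_f):
            raise ValueError("swc_override exceeds field capacity")
        return pd.Series(values, index=days, name="SWC")

    if config.state_plan is not None:
        return pd.Series(
            _plan_consistent_swc(config, rng), index=days, name="SWC"
        )

    lo, hi = profile.sweep_range
    if config.irrigation_days:
        events = dict(zip(config.irrigation_days, config.irrigation_depths))
        cycle = None
    else:
        events, cycle = {}, 25
    floor = lo - 2.0  # asymptotic drawdown level, below the driest planted day
    # decay rate chosen so an uninterrupted 24-day drawdown from hi reaches lo
    k = np.log((hi - floor) / (lo - floor)) / 24.0
    swc = config.swc0 if config.swc0 is not None else hi
    values = np.empty(config.n_days)
    for d in range(config.n_days):
        if d > 0:
            swc = floor + (swc - floor) * np.exp(-k)
            if cycle is not None and d % cycle == 0:
                swc = hi
            elif d in events:
                swc = min(swc + 0.2 * events[d], profile.theta_f)
        values[d] = min(swc + rng.normal(0.0, 0.08), profile.theta_f)
    return pd.Series(values, index=days, name="SWC")


def _plan_consistent_swc(config: SeasonConfig, rng: np.random.Generator) -> np.ndarray:
    """Daily SWC honouring an explicit state plan.

    Each maximal run of same-state days gets a linear drawdown within the
    state's admissible range (reset at the run start, like an irrigation
    event), plus small jitter that never crosses the planted bounds.
    Deficit treatments sit lower in the State-I range than full
    treatments, and drawdowns pass through the ambiguous band [L*, U*]
    on both sides, so the same soil water can carry either state - the
    structure that makes substate modeling genuinely informative.
    """
    profile = config.profile
    plan = ["II" if s.startswith("II") else "I" for s in config.state_plan]
    if len(plan) != config.n_days:
        raise ValueError("state_plan length must equal n_days")
    full = profile.scales(config.treatment) == (1.0, 1.0)
    if full:
        hi_I = min(profile.theta_f - 2.0, profile.upper_bound + 5.5)
        lo_I = profile.upper_bound - 0.8  # dips into the ambiguous band
    else:
        hi_I = profile.upper_bound + 1.5
        lo_I = profile.lower_bound + 0.2
    hi_II = profile.upper_bound - 0.3  # stress can begin inside the band
    lo_II = profile.lower_bound - 4.5

    values = np.empty(config.n_days)
    d = 0
    while d < config.n_days:
        run = d
        while run < config.n_days and plan[run] == plan[d]:
            run += 1
        n = run - d
        hi, lo = (hi_I, lo_I) if plan[d] == "I" else (hi_II, lo_II)
        ramp = np.linspace(hi, lo, n) if n > 1 else np.array([(hi + lo) / 2.0])
        ramp = ramp + rng.normal(0.0, 0.08, size=n)
        if plan[d] == "I":
            ramp = ramp.clip(profile.lower_bound + 0.1, profile.theta_f)
        else:
            ramp = ramp.clip(None, profile.upper_bound - 0.1)
        values[d:run] = ramp
        d = run
    return values


def assign_states(
    daily_swc: pd.Series,
    profile: CropProfile,
    seed: int = 0,
    p_state1_band: float = 0.5,
    subtype_mode: str = "by_depth",
) -> pd.DataFrame:
    """Plant a per-day state from soil water: the SWC switching rule.

    SWC above U* -> State I; below L* -> State II; within [L*, U*] a
    seeded Bernoulli draw (P(State I) = ``p_state1_band``). State-II
    subtypes default to the stress-depth rule (N for mild deficit below
    L*, M moderate, V severe - the curve inverts progressively as the
    soil dries); ``subtype_mode="mixture"`` draws from the renormalised
    N/M/V frequency weights instead.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for date, swc in daily_swc.items():
        if swc > profile.upper_bound:
            state = "I"
        elif swc < profile.lower_bound:
            state = "II"
        else:
            state = "I" if rng.random() < p_state1_band else "II"
        if state == "I":
            subtype = "none"
        elif subtype_mode == "by_depth":
            depth = profile.lower_bound - swc
            subtype = "N" if depth < 1.5 else ("M" if depth < 3.0 else "V")
        elif subtype_mode == "mixture":
            subtype = rng.choice(["N", "M", "V"], p=np.array(profile.subtype_weights))
        else:
            raise ValueError(f"unknown subtype_mode {subtype_mode!r}")
        rows.append({"date": date, "state": state, "subtype": subtype, "SWC": swc})
    return pd.DataFrame(rows)


def render_pp(
    plan: pd.DataFrame,
    meteo: pd.DataFrame,
    profile: CropProfile,
    config: SeasonConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the P_p series for a per-day state plan.

    Each day evaluates its state template scaled to that day's level and
    amplitude: level = night_base * (1 + level_coef * stress(SWC)),
    amplitude = amplitude * (1 + amp_level_coef * stress) * (day's Rs
    peak / nominal), with State-II curves flattened and the treatment's
    min/max scales applied to level and amplitude. Additive Gaussian
    noise has s.d. ``sigma`` times the daily range; all samples stay
    positive. Returns the turgor series and the ground truth (planted
    state, subtype, SWC, realized level/amplitude per day).
    """
    *_, rng = _rng_streams(config.seed, 4)
    max_scale, min_scale = profile.scales(config.treatment)
    meteo = meteo.copy()
    meteo_dates = meteo["timestamp"].dt.normalize()

    records, truth_rows = [], []
    for _, day in plan.iterrows():
        date = pd.Timestamp(day["date"]).normalize()
        day_meteo = meteo.loc[meteo_dates == date]
        if len(day_meteo) != SLOTS_PER_DAY:
            raise ValueError(f"meteorology does not cover {date.date()}")
        key = day["subtype"] if day["state"] == "II" else "I"
        if key not in _TEMPLATES:
            raise ValueError(f"unknown subtype {key!r}")
        stress = float(profile.stress(day["SWC"], state=day["state"]))
        a_d = float(day_meteo["Rs"].max()) / profile.rs_amp
        base = profile.night_base * (1.0 + profile.level_coef * stress) * min_scale
        amp = (
            profile.amplitude
            * (1.0 + profile.amp_level_coef * stress)
            * a_d
            * max_scale
        )
        if day["state"] == "II":
            amp *= profile.state2_amp_factor
        curve = base + amp * _template_curve(key)
        if config.sigma > 0:
            rng_day = curve.max() - curve.min()
            curve = curve + rng.normal(0.0, config.sigma * rng_day, size=curve.size)
        curve = np.maximum(curve, 0.1)
        records.append(
            pd.DataFrame({"timestamp": day_meteo["timestamp"].to_numpy(), "P_p": curve})
        )
        truth_rows.append(
            {
                "date": date,
                "state": day["state"],
                "subtype": day["subtype"],
                "SWC": day["SWC"],
                "base": base,
                "amplitude": amp,
            }
        )
    turgor = pd.concat(records, ignore_index=True)
    turgor["treatment"] = config.treatment
    truth = pd.DataFrame(truth_rows)
    truth["treatment"] = config.treatment
    return turgor, truth


def generate_season(config: SeasonConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compose a full labeled season: (merged dataset, ground truth).

    The dataset has the canonical merged-CSV layout and round-trips
    through the ingest module; the ground truth carries the planted
    per-day state/subtype and realized template parameters, and is never
    consumed by the pipeline under test.
    """
    meteo = simulate_meteorology(config)
    swc_daily = simulate_swc(config)
    if config.state_plan is not None:
        plan = pd.DataFrame(
            {
                "date": swc_daily.index,
                "state": ["II" if s.startswith("II") else "I" for s in config.state_plan],
                "subtype": [
                    s.split("-", 1)[1] if s.startswith("II-") else None
                    for s in config.state_plan
                ],
                "SWC": swc_daily.to_numpy(),
            }
        )
        # Subtypes not pinned by the plan follow the stress-depth rule.
        depth = config.profile.lower_bound - plan["SWC"]
        derived = np.where(depth < 1.5, "N", np.where(depth < 3.0, "M", "V"))
        plan["subtype"] = np.where(
            plan["state"] == "I",
            "none",
            plan["subtype"].fillna(pd.Series(derived, index=plan.index)),
        )
    else:
        plan = assign_states(
            swc_daily,
            config.profile,
            seed=config.seed,
            p_state1_band=config.p_state1_band,
            subtype_mode=config.subtype_mode,
        )
    turgor, truth = render_pp(plan, meteo, config.profile, config)
    dataset = ingest.merge_to_grid(meteo, turgor, swc_daily, treatment=config.treatment)
    return dataset, truth


# --- fixed benchmark scenarios -------------------------------------------
# Season lengths (65 and 60 days) are back-derived from the reported
# State-I percentages; the explicit plans place the stressed (State II)
# episodes the way they occurred: a short mid-season episode under full
# irrigation, most of the season under tomato deficit irrigation, and the
# late season for celery.


def _plan(n_days: int, state2_days: set[int]) -> tuple[str, ...]:
    return tuple("II" if d in state2_days else "I" for d in range(n_days))


def _scenario_configs() -> dict[str, dict]:
    return {
        "tomato-TB-2021": dict(
            profile=TOMATO, treatment="TB", n_days=65, start="2021-07-01",
            state_plan=_plan(65, set(range(30, 34))),  # 61 I / 4 II
        ),
        "tomato-T0-2021": dict(
            profile=TOMATO, treatment="T0", n_days=65, start="2021-07-01",
            state_plan=_plan(65, set(range(65)) - set(range(0, 5)) - set(range(33, 38))),
            # 10 I / 55 II: brief recoveries right after irrigation
        ),
        "celery-CFI-2022": dict(
            profile=CELERY, treatment="CFI", n_days=60, start="2022-11-15",
            state_plan=_plan(60, set(range(42, 60))),  # 42 I / 18 II
        ),
        "celery-CDI-2022": dict(
            profile=CELERY, treatment="CDI", n_days=60, start="2022-11-15",
            state_plan=_plan(60, set(range(35, 60))),  # 35 I / 25 II
        ),
    }


SCENARIO_NAMES = tuple(_scenario_configs())


def scenario_config(name: str, seed: int = 0, sigma: float | None = None) -> SeasonConfig:
    """Config for one fixed benchmark scenario (seed and noise adjustable)."""
    table = _scenario_configs()
    if name not in table:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(table)}")
    kwargs = table[name]
    if sigma is not None:
        kwargs = dict(kwargs, sigma=sigma)
    return SeasonConfig(seed=seed, scenario=name, **kwargs)


def benchmark_seasons(
    seed: int = 0, sigma: float | None = None
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Generate the standard two-crop, four-treatment benchmark season set."""
    out = {}
    for i, name in enumerate(SCENARIO_NAMES):
        cfg = scenario_config(name, seed=seed + i, sigma=sigma)
        out[name] = generate_season(cfg)
    return out


def sweep_config(
    profile: CropProfile, n_days: int = 200, seed: int = 0, cycle: int = 25, **kwargs
) -> SeasonConfig:
    """A long drawdown-cycle season spanning the profile's full SWC range.

    Irrigation refills to the top of ``profile.sweep_range`` every
    ``cycle`` days and the soil dries linearly to the bottom, so the
    season samples SWC densely near the planted state bounds - the
    standard input for threshold-recovery studies.
    """
    lo, hi = profile.sweep_range
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    cycles = int(np.ceil(n_days / cycle))
    ramp = np.concatenate([np.linspace(hi, lo, cycle) for _ in range(cycles)])[:n_days]
    swc = np.clip(ramp + rng.normal(0.0, 0.05, size=n_days), lo, hi)
    first_treatment = profile.treatment_scales[0][0]
    return SeasonConfig(
        profile=profile,
        treatment=kwargs.pop("treatment", first_treatment),
        n_days=n_days,
        seed=seed,
        swc_override=tuple(swc),
        **kwargs,
    )
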