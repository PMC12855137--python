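import numpy as np
import pandas as pd
import pytest

import leafturgor as lt
from leafturgor import DailyCurve
from leafturgor.config import SLOTS_PER_DAY

HOURS = np.arange(SLOTS_PER_DAY) / 12.0


def make_curve(values, date="2021-07-01", treatment="TB"):
    return DailyCurve(pd.Timestamp(date), np.asarray(values, dtype=float), treatment)


@pytest.fixture(scope="session")
def hours():
    return HOURS


@pytest.fixture(scope="session")
def unimodal_curve():
    """State-I-like template: flat night, morning rise, midday peak, decay."""
    v = 20.0 + 50.0 * np.exp(-0.5 * ((HOURS - 13.0) / 3.0) ** 2)
    return make_curve(v)


@pytest.fixture(scope="session")
def trough_curve():
    """State-II 'V'-like template: high night, pronounced midday minimum."""
    v = 70.0 - 50.0 * np.exp(-0.5 * ((HOURS - 12.5) / 3.0) ** 2)
    return make_curve(v)


@pytest.fixture(scope="session")
def twin_peak_curve():
    """State-II 'M'-like template: maxima ~10:30 and ~16:30, midday trough,
    rising morning window and falling evening window."""
    v = (
        20.0
        + 45.0 * np.exp(-0.5 * ((HOURS - 10.5) / 1.6) ** 2)
        + 50.0 * np.exp(-0.5 * ((HOURS - 16.5) / 1.6) ** 2)
    )
    return make_curve(v)


@pytest.fixture(scope="session")
def small_season():
    """A short seeded sweep season shared by the cheaper model tests."""
    cfg = lt.sweep_config(lt.TOMATO, n_days=24, seed=123, cycle=12)
    dataset, truth = lt.generate_season(cfg)
    curves, _ = lt.extract_daily_curves(dataset)
    labels = lt.label_days(curves)
    return dataset, truth, labels
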