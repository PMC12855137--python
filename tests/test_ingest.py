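import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafturgor import (
    compute_vpd,
    gap_report,
    interpolate_swc,
    merge_to_grid,
    read_dataset,
    read_logger_csv,
    write_dataset,
)
from leafturgor.config import SLOTS_PER_DAY


class TestComputeVpd:
    def test_saturated_air_gives_zero(self):
        assert compute_vpd(25.0, 100.0) == 0.0

    def test_dry_air_matches_closed_form(self):
        # independently evaluated: 0.611 * exp(17.502*20 / 260.97)
        assert compute_vpd(20.0, 0.0) == pytest.approx(2.336479427548824, abs=1e-12)

    def test_linear_in_saturation_deficit(self):
        assert compute_vpd(20.0, 50.0) == pytest.approx(
            compute_vpd(20.0, 0.0) / 2.0, abs=1e-12
        )

    def test_agrees_with_independent_evaluation_on_lattice(self):
        T, RH = np.meshgrid(np.linspace(-5, 45, 10), np.linspace(0, 100, 10))
        got = compute_vpd(T, RH)
        for t, rh, v in zip(T.ravel(), RH.ravel(), np.asarray(got).ravel()):
            expected = 0.611 * math.exp(17.502 * t / (t + 240.97)) * (1 - rh / 100.0)
            assert abs(v - expected) < 1e-9

    @given(
        t=st.floats(-19.9, 59.9),
        rh=st.floats(0.0, 100.0),
        dt=st.floats(0.01, 5.0),
        drh=st.floats(0.01, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_temperature_and_humidity(self, t, rh, dt, drh):
        base = compute_vpd(t, rh)
        assert base >= 0.0
        if t + dt < 60.0:
            assert compute_vpd(t + dt, rh) >= base
        if rh + drh <= 100.0:
            assert compute_vpd(t, rh + drh) <= base

    @pytest.mark.parametrize("rh", [-0.1, 100.1])
    def test_rejects_humidity_outside_percent_range(self, rh):
        with pytest.raises(ValueError, match="humidity"):
            compute_vpd(20.0, rh)

    def test_rejects_implausible_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            compute_vpd(-250.0, 50.0)  # below the singular denominator


class TestInterpolateSwc:
    def test_midpoint_of_linear_segment(self):
        s = interpolate_swc([("2021-07-01", 20.0), ("2021-07-11", 30.0)])
        assert s.loc["2021-07-06"] == pytest.approx(25.0)
        assert s.loc["2021-07-01"] == 20.0 and s.loc["2021-07-11"] == 30.0
        assert len(s) == 11

    def test_constant_over_all_grid_slots_of_a_day(self):
        s = interpolate_swc([("2021-07-01", 20.0), ("2021-07-11", 30.0)])
        # one value per calendar day; the merge broadcasts it to all 288 slots
        day5 = s.loc["2021-07-06"]
        meteo = _one_day_meteo("2021-07-06")
        turgor = meteo[["timestamp"]].assign(P_p=30.0)
        merged = merge_to_grid(meteo, turgor, s)
        assert (merged["SWC"] == day5).all()
        assert len(merged) == SLOTS_PER_DAY

    def test_piecewise_linear_second_difference_constant(self):
        s = interpolate_swc([("2021-07-01", 18.0), ("2021-07-13", 30.0)])
        second = np.diff(s.to_numpy(), 2)
        assert np.allclose(second, 0.0, atol=1e-12)

    def test_duplicate_dates_are_averaged(self):
        s = interpolate_swc(
            [("2021-07-01", 20.0), ("2021-07-01", 22.0), ("2021-07-03", 25.0)]
        )
        assert s.iloc[0] == pytest.approx(21.0)

    def test_single_observation_needs_hold_policy(self):
        with pytest.raises(ValueError, match="two SWC observations"):
            interpolate_swc([("2021-07-01", 20.0)])
        held = interpolate_swc(
            [("2021-07-01", 20.0)], span=("2021-07-01", "2021-07-03"), edge="hold"
        )
        assert (held == 20.0).all() and len(held) == 3

    def test_span_beyond_observations_rejected_unless_hold(self):
        obs = [("2021-07-02", 20.0), ("2021-07-04", 24.0)]
        with pytest.raises(ValueError, match="beyond the observation range"):
            interpolate_swc(obs, span=("2021-07-01", "2021-07-05"))
        held = interpolate_swc(obs, span=("2021-07-01", "2021-07-05"), edge="hold")
        assert held.iloc[0] == 20.0 and held.iloc[-1] == 24.0


def _one_day_meteo(date="2021-07-01", n=SLOTS_PER_DAY):
    ts = pd.date_range(date, periods=n, freq="5min")
    return pd.DataFrame(
        {"timestamp": ts, "Rs": 100.0, "T": 25.0, "RH": 60.0, "WS": 0.2}
    )


class TestLoggerCsvRoundTrip:
    def test_complete_day_has_full_grid(self, tmp_path):
        path = tmp_path / "day.csv"
        _one_day_meteo().to_csv(path, index=False)
        df = read_logger_csv(path)
        assert len(df) == SLOTS_PER_DAY
        assert gap_report(df).empty

    def test_missing_slot_appears_in_gap_report(self, tmp_path):
        path = tmp_path / "gappy.csv"
        _one_day_meteo().drop(index=[10]).to_csv(path, index=False)
        df = read_logger_csv(path)
        report = gap_report(df)
        assert len(report) == 1
        assert report["timestamp"].iloc[0] == pd.Timestamp("2021-07-01 00:50:00")

    def test_round_trip_is_value_identical(self, tmp_path):
        src = tmp_path / "src.csv"
        dst = tmp_path / "dst.csv"
        meteo = _one_day_meteo()
        meteo.to_csv(src, index=False)
        df = read_logger_csv(src)
        write_dataset(df, dst)
        again = read_dataset(dst)
        pd.testing.assert_frame_equal(
            df.reset_index(drop=True), again[df.columns], check_dtype=False
        )

    def test_unparseable_timestamp_reported_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        frame = _one_day_meteo(n=5).astype({"timestamp": str})
        frame.loc[2, "timestamp"] = "not-a-time"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="rows 4"):
            read_logger_csv(path)

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "mono.csv"
        frame = _one_day_meteo(n=5)
        frame = frame.iloc[[0, 2, 1, 3, 4]]
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="not increasing"):
            read_logger_csv(path)

    def test_unknown_columns_rejected_when_schema_declared(self, tmp_path):
        path = tmp_path / "extra.csv"
        _one_day_meteo(n=5).assign(bogus=1).to_csv(path, index=False)
        with pytest.raises(ValueError, match="bogus"):
            read_logger_csv(path, columns={c: c for c in ["Rs", "T", "RH", "WS"]})


class TestMergeToGrid:
    def test_ten_common_days_give_2880_rows(self):
        ts = pd.date_range("2021-07-01", periods=10 * SLOTS_PER_DAY, freq="5min")
        meteo = pd.DataFrame(
            {"timestamp": ts, "Rs": 50.0, "T": 22.0, "RH": 70.0, "WS": 0.1}
        )
        turgor = pd.DataFrame({"timestamp": ts, "P_p": 30.0})
        swc = interpolate_swc([("2021-07-01", 20.0), ("2021-07-10", 25.0)])
        merged = merge_to_grid(meteo, turgor, swc, treatment="TB")
        assert len(merged) == 2880
        assert list(merged.columns[:9]) == [
            "timestamp", "Rs", "T", "RH", "WS", "VPD", "SWC", "P_p", "treatment",
        ]
        # exactly one distinct SWC value per calendar day
        per_day = merged.groupby(merged["timestamp"].dt.normalize())["SWC"].nunique()
        assert (per_day == 1).all()

    def test_day_missing_from_turgor_is_excluded(self):
        ts = pd.date_range("2021-07-01", periods=3 * SLOTS_PER_DAY, freq="5min")
        meteo = pd.DataFrame(
            {"timestamp": ts, "Rs": 50.0, "T": 22.0, "RH": 70.0, "WS": 0.1}
        )
        keep = ts.normalize() != pd.Timestamp("2021-07-02")
        turgor = pd.DataFrame({"timestamp": ts[keep], "P_p": 30.0})
        swc = interpolate_swc([("2021-07-01", 20.0), ("2021-07-03", 25.0)])
        merged = merge_to_grid(meteo, turgor, swc)
        days = merged["timestamp"].dt.normalize().unique()
        assert pd.Timestamp("2021-07-02") not in days
        assert len(merged) == 2 * SLOTS_PER_DAY

    def test_empty_overlap_rejected(self):
        meteo = _one_day_meteo("2021-07-01")
        turgor = _one_day_meteo("2021-08-01")[["timestamp"]].assign(P_p=30.0)
        swc = interpolate_swc([("2021-07-01", 20.0), ("2021-08-02", 25.0)])
        with pytest.raises(ValueError, match="no overlapping"):
            merge_to_grid(meteo, turgor, swc)

    def test_merge_never_fabricates_values(self):
        meteo = _one_day_meteo()
        turgor = meteo[["timestamp"]].assign(P_p=np.arange(SLOTS_PER_DAY, dtype=float))
        swc = interpolate_swc(
            [("2021-07-01", 20.0)], span=("2021-07-01", "2021-07-01"), edge="hold"
        )
        merged = merge_to_grid(meteo, turgor, swc)
        assert merged["P_p"].tolist() == turgor["P_p"].tolist()
        assert (merged["Rs"] == meteo["Rs"].to_numpy()).all()
        assert (merged["SWC"] == 20.0).all()
        assert not merged.isna().any().any()
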