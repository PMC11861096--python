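"""Thermal-time engine: daily contributions, accumulation, stage profiles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermalgxe as tg
from thermalgxe.thermal import StageLabel, stage_windows

from conftest import START, weather_from_pairs, window


def day(tmin, tmax):
    return tg.DailyWeather(START, tmin, tmax)


class TestDailyContribution:
    @pytest.mark.parametrize(
        "tmin,tmax,base,ceiling,expected",
        [
            (10, 30, 10, 30, 10.0),  # no capping engaged
            (2, 8, 10, 30, 0.0),  # entire day below base
            (20, 35, 10, 30, 15.0),  # ceiling caps tmax
            (20, 35, 10, 50, 17.5),  # higher ceiling releases the cap
            (5, 25, 10, 30, 7.5),  # floor lifts tmin to base
        ],
    )
    def test_examples(self, tmin, tmax, base, ceiling, expected):
        got = tg.daily_degree_contribution(day(tmin, tmax), base, ceiling)
        assert got == pytest.approx(expected)

    def test_cap_max_only_keeps_cold_nights(self):
        d = day(5, 25)
        assert tg.daily_degree_contribution(d, 10, 30, "cap_max_only") == pytest.approx(5.0)

    def test_rejects_inverted_day(self):
        with pytest.raises(ValueError, match="tmax"):
            tg.DailyWeather(START, 20, 10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            tg.DailyWeather(START, float("nan"), 10)

    def test_rejects_base_above_ceiling(self):
        with pytest.raises(ValueError, match="base"):
            tg.daily_degree_contribution(day(10, 20), base=30, ceiling=10)


class TestAccumulation:
    def test_three_identical_days(self):
        wx = weather_from_pairs([(10, 30)] * 3)
        assert tg.accumulate_gdd(wx, window(3)) == pytest.approx(30.0)

    def test_single_day_window(self):
        wx = weather_from_pairs([(10, 20)])
        assert tg.accumulate_gdd(wx, window(1)) == pytest.approx(5.0)

    def test_all_below_base_is_zero(self):
        wx = weather_from_pairs([(0, 8), (1, 9), (-2, 5)])
        assert tg.accumulate_gdd(wx, window(3)) == 0.0

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError, match="after"):
            tg.StageWindow(START + dt.timedelta(days=1), START)

    def test_missing_date_named_in_error(self):
        wx = weather_from_pairs([(10, 30)] * 5)
        gap = wx.drop(index=2)
        with pytest.raises(tg.WeatherGapError, match="2019-05-03"):
            tg.accumulate_gdd(gap, window(5))

    def test_duplicate_dates_rejected(self):
        wx = weather_from_pairs([(10, 30)] * 3)
        with pytest.raises(ValueError, match="duplicate"):
            tg.accumulate_gdd(pd.concat([wx, wx.iloc[[0]]]), window(3))


class TestSdd:
    def test_zero_when_never_above_growth_ceiling(self):
        wx = weather_from_pairs([(12, 28), (10, 30), (8, 25)])
        assert tg.compute_sdd(wx, window(3)) == 0.0

    def test_ten_hot_days(self):
        wx = weather_from_pairs([(20, 35)] * 10)
        assert tg.compute_sdd(wx, window(10)) == pytest.approx(25.0)

    def test_stress_ceiling_caps_extreme_day(self):
        wx = weather_from_pairs([(25, 55)])
        assert tg.compute_sdd(wx, window(1)) == pytest.approx(10.0)


class TestGrowDays:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(10, 30)] * 5, 5),
            ([(1, 9)] * 5, 0),
            ([(10, 30), (1, 9), (12, 25), (0, 5), (15, 28)], 3),
        ],
    )
    def test_counts(self, pairs, expected):
        wx = weather_from_pairs(pairs)
        assert tg.count_grow_days(wx, window(len(pairs))) == expected


class _Plot:
    def __init__(self, sowing, flowering, maturity, plot_id="p1", location="loc"):
        self.sowing_date = sowing
        self.flowering_date = flowering
        self.maturity_date = maturity
        self.plot_id = plot_id
        self.location = location


class TestStageProfiles:
    def test_constant_weather_splits_evenly(self):
        wx = weather_from_pairs([(20, 35)] * 4)
        plot = _Plot(START, START + dt.timedelta(days=2), START + dt.timedelta(days=3))
        prof = tg.stage_thermal_profile(plot, wx)
        veg, rep, full = (
            prof["vegetative"], prof["reproductive"], prof["full_season"],
        )
        assert veg.gdd == pytest.approx(rep.gdd) == pytest.approx(30.0)
        assert veg.sdd == pytest.approx(rep.sdd) == pytest.approx(5.0)
        assert full.gdd == pytest.approx(veg.gdd + rep.gdd)
        assert full.sdd == pytest.approx(veg.sdd + rep.sdd)
        assert full.grow_days == veg.grow_days + rep.grow_days
        assert full.age_days == veg.age_days + rep.age_days == 4

    def test_flowering_on_sowing_gives_empty_vegetative(self):
        wx = weather_from_pairs([(10, 30)] * 3)
        plot = _Plot(START, START, START + dt.timedelta(days=2))
        prof = tg.stage_thermal_profile(plot, wx)
        assert prof["vegetative"] == tg.ThermalProfile(0.0, 0.0, 0, 0)
        assert prof["full_season"].gdd == pytest.approx(prof["reproductive"].gdd)

    def test_out_of_order_dates_name_the_plot(self):
        wx = weather_from_pairs([(10, 30)] * 3)
        plot = _Plot(START + dt.timedelta(days=2), START, START, plot_id="bad-plot")
        with pytest.raises(ValueError, match="bad-plot"):
            tg.stage_thermal_profile(plot, wx)

    def test_profiles_table_matches_per_plot_recomputation(self, default_trial):
        plots = default_trial["plots"][:25]
        table = tg.profiles_table(plots, default_trial["weather"])
        for plot in plots:
            prof = tg.stage_thermal_profile(plot, default_trial["weather"][plot.location])
            sub = table.loc[table["plot_id"] == plot.plot_id].set_index("stage")
            for stage, expected in prof.items():
                row = sub.loc[stage]
                assert row["gdd"] == pytest.approx(expected.gdd)
                assert row["sdd"] == pytest.approx(expected.sdd)
                assert row["grow_days"] == expected.grow_days
                assert row["age_days"] == expected.age_days


def brute_force_gdd(pairs, base, ceiling, rule="cap_max_floor_min"):
    """Oracle: materialise every day's capped temperatures explicitly."""
    total = 0.0
    for tmin, tmax in pairs:
        t_hi = min(tmax, ceiling)
        t_lo = max(tmin, base) if rule == "cap_max_floor_min" else tmin
        total += max(0.0, (t_hi + t_lo) / 2 - base)
    return total


temp_pairs = st.lists(
    st.tuples(
        st.floats(min_value=-15, max_value=38),
        st.floats(min_value=0, max_value=17),
    ).map(lambda p: (round(p[0], 2), round(p[0] + p[1], 2))),
    min_size=1,
    max_size=60,
)


class TestProperties:
    @settings(max_examples=150, derandomize=True)
    @given(pairs=temp_pairs, rule=st.sampled_from(["cap_max_floor_min", "cap_max_only"]))
    def test_matches_brute_force_oracle(self, pairs, rule):
        wx = weather_from_pairs(pairs)
        win = window(len(pairs))
        for ceiling in (30.0, 50.0):
            assert tg.accumulate_gdd(wx, win, 10, ceiling, rule) == pytest.approx(
                brute_force_gdd(pairs, 10, ceiling, rule)
            )

    @settings(max_examples=100, derandomize=True)
    @given(pairs=temp_pairs)
    def test_sdd_non_negative_and_identity(self, pairs):
        wx = weather_from_pairs(pairs)
        win = window(len(pairs))
        cfg = tg.ThermalConfig()
        sdd = tg.compute_sdd(wx, win, cfg)
        assert sdd >= 0
        assert sdd == pytest.approx(
            tg.accumulate_gdd(wx, win, ceiling=50) - tg.accumulate_gdd(wx, win, ceiling=30)
        )

    @settings(max_examples=60, derandomize=True)
    @given(pairs=temp_pairs.filter(lambda p: len(p) >= 2))
    def test_gdd_monotone_in_window_and_ceiling(self, pairs):
        wx = weather_from_pairs(pairs)
        cums = [tg.accumulate_gdd(wx, window(n)) for n in range(1, len(pairs) + 1)]
        assert all(b >= a for a, b in zip(cums, cums[1:]))
        win = window(len(pairs))
        assert tg.accumulate_gdd(wx, win, ceiling=50) >= tg.accumulate_gdd(wx, win, ceiling=30)
        assert tg.accumulate_gdd(wx, win, base=10, ceiling=30) >= tg.accumulate_gdd(
            wx, win, base=15, ceiling=30
        )

    @settings(max_examples=60, derandomize=True)
    @given(pairs=temp_pairs.filter(lambda p: len(p) >= 3), data=st.data())
    def test_additive_over_partition(self, pairs, data):
        wx = weather_from_pairs(pairs)
        split = data.draw(st.integers(min_value=1, max_value=len(pairs) - 1))
        left = tg.StageWindow(START, START + dt.timedelta(days=split - 1))
        right = tg.StageWindow(
            START + dt.timedelta(days=split), START + dt.timedelta(days=len(pairs) - 1)
        )
        whole = window(len(pairs))
        for fn in (tg.accumulate_gdd, tg.compute_sdd):
            assert fn(wx, whole) == pytest.approx(fn(wx, left) + fn(wx, right))


def test_stage_windows_are_disjoint_and_cover_season():
    sowing = START
    flowering = START + dt.timedelta(days=40)
    maturity = START + dt.timedelta(days=100)
    wins = stage_windows(sowing, flowering, maturity)
    veg, rep, full = (
        wins[StageLabel.vegetative], wins[StageLabel.reproductive], wins[StageLabel.full_season],
    )
    assert veg.end_date + dt.timedelta(days=1) == rep.start_date
    assert (full.start_date, full.end_date) == (sowing, maturity)
    assert veg.n_days + rep.n_days == full.n_days
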