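"""Thermal-time accumulation: Growing Degree Days and Stress Degree Days.

Thermal time indexes crop development on accumulated temperature rather than
calendar days.  Each day contributes the capped daily mean temperature in
excess of a crop base temperature:

    GDD = sum over days of max(0, (Tmax' + Tmin')/2 - Tbase)

where Tmax' is the daily maximum capped at a growth ceiling (temperatures
above it do not speed development) and, under the default capping rule,
Tmin' is the daily minimum floored at the base.  Stress Degree Days isolate
the heat load above the growth ceiling by differencing two GDD runs:

    SDD = GDD(ceiling = stress ceiling) - GDD(ceiling = growth ceiling)

With the chickpea defaults (base 10 °C, growth ceiling 30 °C, stress ceiling
50 °C chosen above any observed maximum) SDD is zero whenever no day exceeds
30 °C and is always non-negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CappingRule",
    "DailyWeather",
    "StageWindow",
    "ThermalConfig",
    "ThermalProfile",
    "WeatherGapError",
    "accumulate_gdd",
    "as_weather_frame",
    "compute_sdd",
    "count_grow_days",
    "daily_degree_contribution",
    "stage_thermal_profile",
]


class CappingRule(str, enum.Enum):
    """How daily extremes are clamped before averaging.

    ``cap_max_floor_min`` (the common agronomic convention, and the default):
    cap Tmax at the ceiling and floor Tmin at the base.  ``cap_max_only``:
    cap Tmax only, leaving cold nights to drag the mean down.  Either way the
    day's contribution is clamped at zero.
    """

    cap_max_floor_min = "cap_max_floor_min"
    cap_max_only = "cap_max_only"


@dataclass(frozen=True)
class DailyWeather:
    """One calendar day's temperature extremes at a location (°C)."""

    date: Date
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tmin) and np.isfinite(self.tmax)):
            raise ValueError(f"non-finite temperature on {self.date}")
        if self.tmax < self.tmin:
            raise ValueError(
                f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}"
            )


@dataclass(frozen=True)
class ThermalConfig:
    """Base and ceiling temperatures for thermal-time runs (°C).

    ``t_base`` is the minimum temperature at which the crop develops,
    ``t_growth_ceiling`` the optimum ceiling above which extra heat does not
    add development, and ``t_stress_ceiling`` an upper bound set above any
    temperature the crop will experience, so that the GDD run it parameterises
    captures all supra-optimal heat.
    """

    t_base: float = 10.0
    t_growth_ceiling: float = 30.0
    t_stress_ceiling: float = 50.0
    capping_rule: CappingRule = CappingRule.cap_max_floor_min

    def __post_init__(self) -> None:
        if not self.t_base < self.t_growth_ceiling < self.t_stress_ceiling:
            raise ValueError(
                "require t_base < t_growth_ceiling < t_stress_ceiling, got "
                f"{self.t_base}, {self.t_growth_ceiling}, {self.t_stress_ceiling}"
            )
        object.__setattr__(self, "capping_rule", CappingRule(self.capping_rule))


class StageLabel(str, enum.Enum):
    vegetative = "vegetative"
    reproductive = "reproductive"
    full_season = "full_season"


@dataclass(frozen=True)
class StageWindow:
    """Inclusive date window attached to a phenological stage."""

    start_date: Date
    end_date: Date
    stage_label: StageLabel = StageLabel.full_season

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"window start {self.start_date} after end {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class ThermalProfile:
    """Accumulated thermal statistics for one stage window.

    ``age_days`` is the inclusive calendar-day count of the window and
    ``grow_days`` the number of those days with a positive degree
    contribution, so 0 <= grow_days <= age_days always holds.
    """

    gdd: float
    sdd: float
    grow_days: int
    age_days: int


class WeatherGapError(ValueError):
    """A date required by a window is missing from the weather series."""


def as_weather_frame(weather) -> pd.DataFrame:
    """Normalise a weather input to a validated, date-sorted DataFrame.

    Accepts a DataFrame with ``date``/``tmin``/``tmax`` columns or an
    iterable of :class:`DailyWeather`.  Dates must be unique; tmax >= tmin
    and finiteness are enforced.
    """
    if isinstance(weather, pd.DataFrame):
        missing = {"date", "tmin", "tmax"} - set(weather.columns)
        if missing:
            raise ValueError(f"weather frame missing columns: {sorted(missing)}")
        frame = weather.loc[:, ["date", "tmin", "tmax"]].copy()
    else:
        rows = list(weather)
        frame = pd.DataFrame(
            {
                "date": [d.date for d in rows],
                "tmin": [d.tmin for d in rows],
                "tmax": [d.tmax for d in rows],
            }
        )
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    frame = frame.sort_values("date", ignore_index=True)
    if frame["date"].duplicated().any():
        dup = frame.loc[frame["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate weather date {dup}")
    tmin = frame["tmin"].to_numpy(float)
    tmax = frame["tmax"].to_numpy(float)
    if not (np.isfinite(tmin).all() and np.isfinite(tmax).all()):
        raise ValueError("non-finite temperature in weather series")
    bad = tmax < tmin
    if bad.any():
        d = frame.loc[bad, "date"].iloc[0]
        raise ValueError(f"tmax < tmin on {d}")
    return frame


def _contributions(
    tmin: np.ndarray,
    tmax: np.ndarray,
    base: float,
    ceiling: float,
    capping_rule: CappingRule | str,
) -> np.ndarray:
    rule = CappingRule(capping_rule)
    tmax_c = np.minimum(tmax, ceiling)
    tmin_c = np.maximum(tmin, base) if rule is CappingRule.cap_max_floor_min else tmin
    return np.maximum(0.0, (tmax_c + tmin_c) / 2.0 - base)


def daily_degree_contribution(
    day: DailyWeather,
    base: float = 10.0,
    ceiling: float = 30.0,
    capping_rule: CappingRule | str = CappingRule.cap_max_floor_min,
) -> float:
    """Degree-day contribution of a single day, never negative."""
    if base >= ceiling:
        raise ValueError(f"base ({base}) must be below ceiling ({ceiling})")
    return float(
        _contributions(
            np.asarray([day.tmin]), np.asarray([day.tmax]), base, ceiling, capping_rule
        )[0]
    )


def _window_arrays(
    weather, window: StageWindow
) -> tuple[np.ndarray, np.ndarray]:
    frame = as_weather_frame(weather)
    mask = (frame["date"] >= window.start_date) & (frame["date"] <= window.end_date)
    sub = frame.loc[mask]
    if len(sub) != window.n_days:
        have = set(sub["date"])
        day = window.start_date
        while day <= window.end_date:
            if day not in have:
                raise WeatherGapError(
                    f"weather series missing {day} inside window "
                    f"[{window.start_date}, {window.end_date}]"
                )
            day += timedelta(days=1)
    return sub["tmin"].to_numpy(float), sub["tmax"].to_numpy(float)


def accumulate_gdd(
    weather,
    window: StageWindow,
    base: float = 10.0,
    ceiling: float = 30.0,
    capping_rule: CappingRule | str = CappingRule.cap_max_floor_min,
) -> float:
    """Sum of daily degree contributions over an inclusive date window."""
    if base >= ceiling:
        raise ValueError(f"base ({base}) must be below ceiling ({ceiling})")
    tmin, tmax = _window_arrays(weather, window)
    return float(_contributions(tmin, tmax, base, ceiling, capping_rule).sum())


def compute_sdd(weather, window: StageWindow, config: ThermalConfig | None = None) -> float:
    """Stress Degree Days: GDD at the stress ceiling minus GDD at the growth ceiling."""
    config = config or ThermalConfig()
    hot = accumulate_gdd(
        weather, window, config.t_base, config.t_stress_ceiling, config.capping_rule
    )
    mild = accumulate_gdd(
        weather, window, config.t_base, config.t_growth_ceiling, config.capping_rule
    )
    return hot - mild


def count_grow_days(
    weather,
    window: StageWindow,
    base: float = 10.0,
    ceiling: float = 30.0,
    capping_rule: CappingRule | str = CappingRule.cap_max_floor_min,
) -> int:
    """Number of days in the window with a positive degree contribution."""
    tmin, tmax = _window_arrays(weather, window)
    return int((_contributions(tmin, tmax, base, ceiling, capping_rule) > 0).sum())


def stage_windows(
    sowing: Date, flowering: Date, maturity: Date
) -> dict[StageLabel, StageWindow | None]:
    """Disjoint, additive stage windows for one plot.

    vegetative = [sowing, flowering - 1 day]; reproductive = [flowering,
    maturity]; full season = [sowing, maturity].  When flowering falls on the
    sowing date the vegetative window is empty and returned as ``None``.
    """
    if not sowing <= flowering <= maturity:
        raise ValueError(
            f"phenology dates out of order: sowing {sowing}, "
            f"flowering {flowering}, maturity {maturity}"
        )
    veg = (
        StageWindow(sowing, flowering - timedelta(days=1), StageLabel.vegetative)
        if flowering > sowing
        else None
    )
    return {
        StageLabel.vegetative: veg,
        StageLabel.reproductive: StageWindow(flowering, maturity, StageLabel.reproductive),
        StageLabel.full_season: StageWindow(sowing, maturity, StageLabel.full_season),
    }


def stage_thermal_profile(
    plot, weather, config: ThermalConfig | None = None
) -> Mapping[str, ThermalProfile]:
    """Thermal profile per stage (vegetative, reproductive, full season).

    ``plot`` needs ``sowing_date``, ``flowering_date``, ``maturity_date``
    attributes (a :class:`~thermalgxe.simulate.PlotRecord` or any namespace).
    Profiles are component-wise additive: the full-season gdd, sdd, grow_days
    and age_days equal the vegetative plus reproductive values.
    """
    config = config or ThermalConfig()
    try:
        windows = stage_windows(
            plot.sowing_date, plot.flowering_date, plot.maturity_date
        )
    except ValueError as exc:
        ident = getattr(plot, "plot_id", "<unknown>")
        raise ValueError(f"plot {ident}: {exc}") from exc

    frame = as_weather_frame(weather)
    out: dict[str, ThermalProfile] = {}
    for label, window in windows.items():
        if window is None:
            out[label.value] = ThermalProfile(0.0, 0.0, 0, 0)
            continue
        tmin, tmax = _window_arrays(frame, window)
        mild = _contributions(
            tmin, tmax, config.t_base, config.t_growth_ceiling, config.capping_rule
        )
        hot = _contributions(
            tmin, tmax, config.t_base, config.t_stress_ceiling, config.capping_rule
        )
        out[label.value] = ThermalProfile(
            gdd=float(mild.sum()),
            sdd=float((hot - mild).sum()),
            grow_days=int((mild > 0).sum()),
            age_days=window.n_days,
        )
    return out


def profiles_table(
    plots: Iterable, weather_by_location: Mapping[str, object], config: ThermalConfig | None = None
) -> pd.DataFrame:
    """Long-format thermal profiles for many plots.

    Precomputes prefix sums of daily contributions per location so cost is
    O(total days + plots), not O(plots x days).  Columns: plot_id, stage,
    age_days, grow_days, gdd, sdd.
    """
    config = config or ThermalConfig()
    pre: dict[str, tuple[np.ndarray, dict[Date, int]]] = {}
    rows = []
    for plot in plots:
        loc = plot.location
        if loc not in pre:
            frame = as_weather_frame(weather_by_location[loc])
            tmin = frame["tmin"].to_numpy(float)
            tmax = frame["tmax"].to_numpy(float)
            mild = _contributions(
                tmin, tmax, config.t_base, config.t_growth_ceiling, config.capping_rule
            )
            hot = _contributions(
                tmin, tmax, config.t_base, config.t_stress_ceiling, config.capping_rule
            )
            dates = list(frame["date"])
            index = {d: i for i, d in enumerate(dates)}
            # verify contiguity once per location; windows then cannot hit gaps
            if dates and (dates[-1] - dates[0]).days + 1 != len(dates):
                day = dates[0]
                have = set(dates)
                while day <= dates[-1]:
                    if day not in have:
                        raise WeatherGapError(
                            f"weather series for {loc} missing {day}"
                        )
                    day += timedelta(days=1)
            cum = np.concatenate([[0.0], np.cumsum(mild)])
            cum_hot = np.concatenate([[0.0], np.cumsum(hot)])
            cum_grow = np.concatenate([[0], np.cumsum(mild > 0)])
            pre[loc] = (np.vstack([cum, cum_hot, cum_grow]), index)

        (cum, cum_hot, cum_grow), index = pre[loc][0], pre[loc][1]
        if plot.maturity_date is None:
            # maturity never scored: only the vegetative stage is available
            if plot.flowering_date > plot.sowing_date:
                veg = StageWindow(
                    plot.sowing_date,
                    plot.flowering_date - timedelta(days=1),
                    StageLabel.vegetative,
                )
                windows = {StageLabel.vegetative: veg}
            else:
                windows = {StageLabel.vegetative: None}
        else:
            windows = stage_windows(
                plot.sowing_date, plot.flowering_date, plot.maturity_date
            )
        for label, window in windows.items():
            if window is None:
                rows.append((plot.plot_id, label.value, 0, 0, 0.0, 0.0))
                continue
            try:
                i0, i1 = index[window.start_date], index[window.end_date] + 1
            except KeyError as exc:
                raise WeatherGapError(
                    f"weather series for {loc} missing {exc.args[0]}"
                ) from exc
            gdd = cum[i1] - cum[i0]
            sdd = (cum_hot[i1] - cum_hot[i0]) - gdd
            rows.append(
                (
                    plot.plot_id,
                    label.value,
                    window.n_days,
                    int(cum_grow[i1] - cum_grow[i0]),
                    float(gdd),
                    float(sdd),
                )
            )
    return pd.DataFrame(
        rows, columns=["plot_id", "stage", "age_days", "grow_days", "gdd", "sdd"]
    )
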