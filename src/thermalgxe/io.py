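"""CSV readers and writers for weather series and plot records.

All tabular I/O is headered CSV: dates ISO-8601, temperatures °C, weights
grams.  Readers validate as they parse and report the offending CSV line
number (header = line 1) on failure.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .simulate import PlotRecord, plots_to_frame
from .thermal import as_weather_frame

__all__ = [
    "read_plots_csv",
    "read_weather_csv",
    "write_plots_csv",
    "write_weather_csv",
]

WEATHER_COLUMNS = ["date", "tmin", "tmax"]
PLOT_COLUMNS = [
    "plot_id", "genotype_id", "location", "tos", "replicate",
    "sowing_date", "flowering_date", "maturity_date",
    "yield_g", "hsw_g", "plot_area_m2",
]


def _parse_date(value, line: int, column: str, optional: bool = False):
    if optional and (value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""):
        return None
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"line {line}: bad {column} {value!r}: {exc}") from exc


def read_weather_csv(path) -> pd.DataFrame:
    """Date-sorted weather frame; duplicate dates and tmax < tmin rejected."""
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = set(WEATHER_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in raw.iterrows():
        line = i + 2
        _parse_date(row["date"], line, "date")
        try:
            tmin, tmax = float(row["tmin"]), float(row["tmax"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line}: malformed temperature: {exc}") from exc
        if not (pd.notna(tmin) and pd.notna(tmax)):
            raise ValueError(f"{path} line {line}: non-finite temperature")
        if tmax < tmin:
            raise ValueError(f"{path} line {line}: tmax ({tmax}) < tmin ({tmin})")
    return as_weather_frame(raw)


def write_weather_csv(weather, path) -> Path:
    path = Path(path)
    frame = as_weather_frame(weather)
    frame.to_csv(path, index=False)
    return path


def read_plots_csv(path) -> list[PlotRecord]:
    """Plot records with phenology date order enforced.

    A missing maturity date is allowed: the record is retained and its
    reproductive/full-season stages are unavailable downstream.
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = set(PLOT_COLUMNS) - {"plot_area_m2"} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in raw.iterrows():
        line = i + 2
        sowing = _parse_date(row["sowing_date"], line, "sowing_date")
        flowering = _parse_date(row["flowering_date"], line, "flowering_date")
        maturity = _parse_date(row["maturity_date"], line, "maturity_date", optional=True)
        try:
            records.append(
                PlotRecord(
                    plot_id=str(row["plot_id"]),
                    genotype_id=int(row["genotype_id"]),
                    location=str(row["location"]),
                    tos=int(row["tos"]),
                    replicate=int(row["replicate"]),
                    sowing_date=sowing,
                    flowering_date=flowering,
                    maturity_date=maturity,
                    yield_g=float(row["yield_g"]),
                    hsw_g=float(row["hsw_g"]),
                    plot_area_m2=float(row.get("plot_area_m2", 8.0)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
    return records


def write_plots_csv(plots, path) -> Path:
    path = Path(path)
    frame = plots_to_frame(plots).loc[:, PLOT_COLUMNS]
    frame.to_csv(path, index=False)
    return path
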