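"""Degree-day phenology and per-line climatic covariates.

Thermal time accumulates daily mean temperature above a 0 degC base from
sowing. Each line's anthesis date in each environment is the first day on
which cumulative degree days reach that line's target (spike-emergence
thermal time plus a fixed offset). Around anthesis two developmental windows
are cut:

* anthesis window: 300 degCd before anthesis to 100 degCd after;
* grain-fill window: 100 degCd to 600 degCd after anthesis;

and within each window the covariates are the average daily maximum, the
number of days with maximum strictly above 30 degC and (grain fill) above
35 degC. Growing-season rainfall (1 May - 31 Oct total) is an
environment-level covariate copied to every line.

Boundary convention (fixed so day counts are reproducible): a window starts
on the first day whose cumulative degree days reach the opening threshold
and ends the day before the closing threshold is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TemperatureSeries

__all__ = [
    "ThermalTimeSeries",
    "AnthesisSchedule",
    "ClimaticCovariate",
    "COVARIATE_NAMES",
    "thermal_time",
    "estimate_anthesis",
    "window_bounds",
    "compute_covariates",
    "make_covariates",
    "covariate_range",
]

COVARIATE_NAMES = (
    "anthesis_avg_max",
    "anthesis_days_gt30",
    "grainfill_avg_max",
    "grainfill_days_gt30",
    "grainfill_days_gt35",
    "gs_rainfall",
)

#: (opening, closing) degree-day offsets relative to anthesis.
WINDOW_DEFS = {"anthesis": (-300.0, 100.0), "grainfill": (100.0, 600.0)}


@dataclass(frozen=True)
class ThermalTimeSeries:
    """Cumulative degree days from sowing, per environment.

    ``ccd`` maps env -> DataFrame(date, ccd); ccd is 0 on the sowing date and
    non-decreasing (daily contribution max(0, (tmin+tmax)/2)).
    """

    ccd: dict
    sowing: dict

    def env_ccd(self, env) -> pd.DataFrame:
        return self.ccd[env]


@dataclass(frozen=True)
class AnthesisSchedule:
    """Estimated anthesis per line x environment.

    ``table`` columns: ``line``, ``env``, ``anthesis_date``, ``anthesis_ccd``
    (the thermal-time target reached on that date).
    """

    table: pd.DataFrame


@dataclass(frozen=True)
class ClimaticCovariate:
    """One climatic covariate: a value per line per environment.

    ``wide`` is lines x environments. The numeric range over all values is
    what normalises responsiveness effects downstream.
    """

    name: str
    wide: pd.DataFrame

    def loc(self, line, env) -> float:
        return float(self.wide.loc[line, env])

    def range(self) -> float:
        vals = self.wide.to_numpy(float)
        return float(np.nanmax(vals) - np.nanmin(vals))

    def env_ranges(self) -> pd.Series:
        return self.wide.max(axis=0) - self.wide.min(axis=0)


def thermal_time(series: TemperatureSeries, sowing_date) -> ThermalTimeSeries:
    """Cumulative degree days (base 0 degC on the daily mean) from sowing.

    ``sowing_date`` is one date for all environments or a dict env -> date.
    Gap days in a temperature record are rejected rather than interpolated.
    """
    ccd = {}
    sowing = {}
    for env, temps in series.temps.items():
        sow = pd.Timestamp(sowing_date[env] if isinstance(sowing_date, dict) else sowing_date)
        dates = pd.to_datetime(temps["date"])
        step = dates.diff().dropna()
        if (step != pd.Timedelta(days=1)).any():
            gap = dates[1:][(step != pd.Timedelta(days=1)).to_numpy()].iloc[0]
            raise ValueError(f"gap in temperature record of {env!r} before {gap.date()}")
        if sow < dates.iloc[0] or sow > dates.iloc[-1]:
            raise ValueError(f"sowing date {sow.date()} outside record for {env!r}")
        daily = np.maximum(0.0, (temps["tmin"].to_numpy(float) + temps["tmax"].to_numpy(float)) / 2.0)
        after = dates > sow  # sowing day itself sits at 0 degCd
        cum = np.where(dates >= sow, np.cumsum(np.where(after, daily, 0.0)), np.nan)
        ccd[env] = pd.DataFrame({"date": dates, "ccd": cum}).dropna().reset_index(drop=True)
        sowing[env] = sow
    return ThermalTimeSeries(ccd, sowing)


def _first_date_reaching(ccd_frame: pd.DataFrame, target: float):
    """First date whose cumulative degree days reach ``target`` (or None)."""
    hit = np.searchsorted(ccd_frame["ccd"].to_numpy(float), target, side="left")
    if hit >= len(ccd_frame):
        return None
    return ccd_frame["date"].iloc[hit]


def estimate_anthesis(
    emergence_ccd: pd.Series,
    offset: float,
    thermal: ThermalTimeSeries,
) -> AnthesisSchedule:
    """Anthesis date per line x environment from thermal-time targets.

    ``emergence_ccd`` gives each line's spike-emergence thermal time at the
    reference environment; the anthesis target adds ``offset`` degCd and the
    anthesis date in every environment is the first day reaching it.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0 degCd")
    rows = []
    failures = []
    for env, frame in thermal.ccd.items():
        for line, em in emergence_ccd.items():
            target = float(em) + offset
            date = _first_date_reaching(frame, target)
            if date is None:
                failures.append((line, env, target - float(frame["ccd"].iloc[-1])))
                continue
            rows.append((line, env, date, target))
    if failures:
        listed = ", ".join(f"{l}@{e} short {s:.0f} degCd" for l, e, s in failures[:5])
        raise ValueError(
            f"{len(failures)} line x environment anthesis targets beyond the "
            f"season's total degree days: {listed}"
        )
    return AnthesisSchedule(
        pd.DataFrame(rows, columns=["line", "env", "anthesis_date", "anthesis_ccd"])
    )


def window_bounds(
    anthesis_ccd: float,
    thermal_env: pd.DataFrame,
    window: str,
):
    """(start date, end date) of a developmental window, inclusive.

    The window opens on the first day cumulative degree days reach
    (anthesis + opening offset) and closes the day before they reach
    (anthesis + closing offset).
    """
    if window not in WINDOW_DEFS:
        raise ValueError(f"unknown window {window!r}")
    lo_off, hi_off = WINDOW_DEFS[window]
    start = _first_date_reaching(thermal_env, anthesis_ccd + lo_off)
    close = _first_date_reaching(thermal_env, anthesis_ccd + hi_off)
    if start is None or close is None:
        total = float(thermal_env["ccd"].iloc[-1])
        short = anthesis_ccd + hi_off - total
        raise ValueError(
            f"{window} window truncated by record end: {short:.0f} degCd short"
        )
    end = close - pd.Timedelta(days=1)
    return start, end


def compute_covariates(
    temps: TemperatureSeries,
    rainfall: dict | None,
    windows: pd.DataFrame,
    include_rainfall: bool = True,
) -> dict:
    """Window summaries per line x environment, as named covariates.

    ``windows`` columns: line, env, window ("anthesis"/"grainfill"), start,
    end (inclusive dates). Returns a dict name -> :class:`ClimaticCovariate`
    with the average daily maximum and strict day counts above 30/35 degC per
    window, plus growing-season rainfall when requested.
    """
    temp_lookup = {}
    for env, frame in temps.temps.items():
        f = frame.copy()
        f["date"] = pd.to_datetime(f["date"])
        temp_lookup[env] = f.set_index("date")["tmax"]
    records: dict[str, list] = {n: [] for n in COVARIATE_NAMES if n != "gs_rainfall"}
    for row in windows.itertuples(index=False):
        tmax = temp_lookup[row.env].loc[pd.Timestamp(row.start):pd.Timestamp(row.end)]
        vals = tmax.to_numpy(float)
        if row.window == "anthesis":
            records["anthesis_avg_max"].append((row.line, row.env, vals.mean()))
            records["anthesis_days_gt30"].append((row.line, row.env, int((vals > 30.0).sum())))
        else:
            records["grainfill_avg_max"].append((row.line, row.env, vals.mean()))
            records["grainfill_days_gt30"].append((row.line, row.env, int((vals > 30.0).sum())))
            records["grainfill_days_gt35"].append((row.line, row.env, int((vals > 35.0).sum())))
    out = {}
    for name, rows in records.items():
        frame = pd.DataFrame(rows, columns=["line", "env", "value"])
        out[name] = ClimaticCovariate(name, frame.pivot(index="line", columns="env", values="value"))
    if include_rainfall:
        if not rainfall:
            raise ValueError("rainfall covariate requested but no rainfall records given")
        lines = out["anthesis_avg_max"].wide.index if out else None
        totals = {}
        for env in temps.temps:
            if env not in rainfall:
                raise ValueError(f"rainfall record missing for environment {env!r}")
            r = rainfall[env].copy()
            r["date"] = pd.to_datetime(r["date"])
            year = int(r["date"].iloc[0].year)
            season = r[(r["date"] >= pd.Timestamp(year=year, month=5, day=1))
                       & (r["date"] <= pd.Timestamp(year=year, month=10, day=31))]
            totals[env] = float(season["mm"].sum())
        wide = pd.DataFrame({env: [totals[env]] * len(lines) for env in temps.temps}, index=lines)
        out["gs_rainfall"] = ClimaticCovariate("gs_rainfall", wide)
    return out


def make_covariates(
    temps: TemperatureSeries,
    schedule: AnthesisSchedule,
    thermal: ThermalTimeSeries,
    rainfall: dict | None = None,
    include_rainfall: bool | None = None,
) -> dict:
    """Windows from the anthesis schedule, then all covariates."""
    rows = []
    for rec in schedule.table.itertuples(index=False):
        for window in WINDOW_DEFS:
            start, end = window_bounds(rec.anthesis_ccd, thermal.env_ccd(rec.env), window)
            rows.append((rec.line, rec.env, window, start, end))
    windows = pd.DataFrame(rows, columns=["line", "env", "window", "start", "end"])
    if include_rainfall is None:
        include_rainfall = bool(rainfall)
    return compute_covariates(temps, rainfall, windows, include_rainfall=include_rainfall)


def covariate_range(cov: ClimaticCovariate) -> float:
    """Numeric range (max - min) of a covariate over all line x environment values."""
    return cov.range()
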