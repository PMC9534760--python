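"""Pond datalogger series and macroclimate tables -> per-population climate.

All summaries are restricted to the population's phenology window — the
calendar interval when larvae occupy the pond. Lowland populations breed in
autumn, so a window may wrap the calendar year (start month-day later than
end month-day).

Micro-scale variables (lowercase, from the logger): tmax = mean daily
maximum over the warmest calendar month in the window, tmin = mean daily
minimum over the coldest month, sr = tmax - tmin, dr = mean daily range
over all qualifying days. Macro-scale (capitals, from monthly tables):
TMAX = max monthly maximum over included months, TMIN = min monthly
minimum, SR reported both as TMAX - TMIN (``SR_extreme``) and as the mean
monthly range (``SR_monthly``).
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LoggerSeries",
    "PhenologyWindow",
    "MacroMonthly",
    "MicroSummary",
    "MacroSummary",
    "ClimateSummary",
    "read_logger_csv",
    "read_macro_csv",
    "read_phenology_csv",
    "clip_to_window",
    "daily_stats",
    "micro_summary",
    "macro_summary",
    "climate_summary",
    "summarize_populations",
]

SANITY_BAND = (-40.0, 60.0)


@dataclass
class LoggerSeries:
    """A pond temperature time series: ``frame`` has columns timestamp, temp_c."""

    population: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"timestamp", "temp_c"} <= set(f.columns):
            raise ValueError("logger frame needs columns 'timestamp' and 'temp_c'")
        if len(f) == 0:
            raise ValueError("empty logger series")
        if not f["timestamp"].is_monotonic_increasing or f["timestamp"].duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        bad = ~f["temp_c"].between(*SANITY_BAND)
        if bad.any():
            logger.warning(
                "%s: %d temperature(s) outside sanity band %s",
                self.population, int(bad.sum()), SANITY_BAND,
            )


@dataclass(frozen=True)
class PhenologyWindow:
    """Larval-period window as inclusive month-day bounds.

    ``start > end`` (as month-day) means the window wraps 31 Dec, e.g.
    autumn-to-spring breeding in the lowlands.
    """

    population: str
    start: tuple[int, int]  # (month, day)
    end: tuple[int, int]

    def __post_init__(self) -> None:
        for m, d in (self.start, self.end):
            if not (1 <= m <= 12 and 1 <= d <= 31):
                raise ValueError(f"bad month-day ({m}, {d})")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        ts = pd.DatetimeIndex(timestamps)
        md = list(zip(ts.month, ts.day))
        key = np.array([m * 100 + d for m, d in md])
        s = self.start[0] * 100 + self.start[1]
        e = self.end[0] * 100 + self.end[1]
        if not self.wraps:
            return (key >= s) & (key <= e)
        return (key >= s) | (key <= e)

    def months_included(self, min_days: int = 15) -> list[int]:
        """Calendar months with at least ``min_days`` days inside the window
        (nominal non-leap year)."""
        months = []
        for month in range(1, 13):
            ndays = calendar.monthrange(2013, month)[1]
            days = pd.date_range(f"2013-{month:02d}-01", periods=ndays, freq="D")
            if int(self.contains(days).sum()) >= min_days:
                months.append(month)
        return months


@dataclass
class MacroMonthly:
    """Monthly macroclimate extremes for one population (12 rows)."""

    population: str
    tmax_c: dict[int, float]  # month -> monthly maximum temperature
    tmin_c: dict[int, float]

    def __post_init__(self) -> None:
        if set(self.tmax_c) != set(range(1, 13)) or set(self.tmin_c) != set(range(1, 13)):
            raise ValueError("need all 12 calendar months")
        for m in range(1, 13):
            if self.tmax_c[m] < self.tmin_c[m]:
                raise ValueError(f"month {m}: monthly max below monthly min")


@dataclass(frozen=True)
class MicroSummary:
    tmax: float
    tmin: float
    sr: float
    dr: float
    warmest_month: int | None
    coldest_month: int | None
    complete_months: bool


@dataclass(frozen=True)
class MacroSummary:
    TMAX: float
    TMIN: float
    SR_extreme: float
    SR_monthly: float
    months: tuple[int, ...]


@dataclass(frozen=True)
class ClimateSummary:
    """Per-population climate over the larval window (Table-style row)."""

    population: str
    TMAX: float
    TMIN: float
    SR: float  # = SR_extreme = TMAX - TMIN
    SR_monthly: float
    tmax: float
    tmin: float
    sr: float  # = tmax - tmin by construction
    dr: float
    window: PhenologyWindow

    def as_row(self) -> dict[str, float | str]:
        return {
            "population": self.population,
            "TMAX": self.TMAX, "tmax": self.tmax,
            "TMIN": self.TMIN, "tmin": self.tmin,
            "SR": self.SR, "SR_monthly": self.SR_monthly,
            "sr": self.sr, "dr": self.dr,
        }


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_logger_csv(path: str | Path, population: str | None = None) -> LoggerSeries:
    """Read a logger CSV (columns timestamp, temp_c; ISO-8601 timestamps).

    Rows are sorted; duplicate timestamps are collapsed to their mean with
    a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty logger file")
    cols = {c.lower(): c for c in df.columns}
    ts_col = cols.get("timestamp")
    temp_col = cols.get("temp_c") or cols.get("temperature")
    if ts_col is None or temp_col is None:
        raise ValueError(f"{path}: need 'timestamp' and 'temp_c' columns")
    try:
        ts = pd.to_datetime(df[ts_col], format="ISO8601")
    except (ValueError, TypeError):
        bad = pd.to_datetime(df[ts_col], format="ISO8601", errors="coerce").isna()
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"{path}: unparseable timestamp at line {line}") from None
    out = pd.DataFrame({"timestamp": ts, "temp_c": pd.to_numeric(df[temp_col])})
    if not out["timestamp"].is_monotonic_increasing:
        logger.warning("%s: out-of-order rows sorted", path)
        out = out.sort_values("timestamp", kind="mergesort")
    if out["timestamp"].duplicated().any():
        logger.warning("%s: duplicate timestamps collapsed by mean", path)
        out = out.groupby("timestamp", as_index=False)["temp_c"].mean()
    return LoggerSeries(
        population=population or path.stem, frame=out.reset_index(drop=True)
    )


def _parse_md(text: str) -> tuple[int, int]:
    m, d = str(text).split("-")
    return int(m), int(d)


def read_phenology_csv(path: str | Path) -> dict[str, PhenologyWindow]:
    """Read phenology windows: columns population, start, end ('MM-DD')."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        w = PhenologyWindow(
            population=row["population"],
            start=_parse_md(row["start"]),
            end=_parse_md(row["end"]),
        )
        out[w.population] = w
    return out


def read_macro_csv(path: str | Path) -> dict[str, MacroMonthly]:
    """Read monthly macro table: columns population, month, tmax_c, tmin_c."""
    df = pd.read_csv(path)
    out = {}
    for pop, grp in df.groupby("population"):
        out[pop] = MacroMonthly(
            population=pop,
            tmax_c={int(r["month"]): float(r["tmax_c"]) for _, r in grp.iterrows()},
            tmin_c={int(r["month"]): float(r["tmin_c"]) for _, r in grp.iterrows()},
        )
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def clip_to_window(series: LoggerSeries, window: PhenologyWindow) -> LoggerSeries:
    """Keep records whose date falls inside the (possibly wrapping) window."""
    mask = window.contains(series.frame["timestamp"])
    if not mask.any():
        raise ValueError(
            f"{series.population}: no logger records inside window "
            f"{window.start}-{window.end}"
        )
    return LoggerSeries(series.population, series.frame.loc[mask].reset_index(drop=True))


def daily_stats(series: LoggerSeries, min_coverage_hours: float = 20.0) -> pd.DataFrame:
    """Per-day max/min/range for days whose records span enough hours.

    A day qualifies when its first and last record are at least
    ``min_coverage_hours`` apart; under-covered days are dropped and
    counted in the ``n_excluded`` frame attribute.
    """
    f = series.frame
    day = f["timestamp"].dt.floor("D")
    grouped = f.groupby(day)
    span_h = (grouped["timestamp"].max() - grouped["timestamp"].min()).dt.total_seconds() / 3600.0
    stats = grouped["temp_c"].agg(["max", "min"])
    keep = span_h >= min_coverage_hours
    n_excluded = int((~keep).sum())
    stats = stats.loc[keep]
    if stats.empty:
        raise ValueError("no day meets the coverage threshold")
    out = pd.DataFrame(
        {
            "date": stats.index,
            "daily_max": stats["max"].to_numpy(),
            "daily_min": stats["min"].to_numpy(),
            "daily_range": (stats["max"] - stats["min"]).to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def micro_summary(
    series: LoggerSeries,
    window: PhenologyWindow,
    min_coverage_hours: float = 20.0,
    min_month_days: int = 20,
) -> MicroSummary:
    """Warmest/coldest-month daily extremes and mean daily range.

    tmax is the mean daily maximum over the warmest calendar month in the
    window (warmest = highest mean daily maximum; ties go to the earlier
    month), tmin symmetrically over the coldest month, sr = tmax - tmin,
    dr = the mean daily range over all qualifying days. If no month has
    at least ``min_month_days`` qualifying days the summary downgrades to
    all-day means of the daily extrema (logged).
    """
    clipped = clip_to_window(series, window)
    days = daily_stats(clipped, min_coverage_hours=min_coverage_hours)
    dr = float(days["daily_range"].mean())
    months = days["date"].dt.to_period("M")
    monthly = days.groupby(months).agg(
        mean_max=("daily_max", "mean"),
        mean_min=("daily_min", "mean"),
        n=("daily_max", "size"),
    )
    full = monthly[monthly["n"] >= min_month_days]
    if full.empty:
        logger.warning(
            "%s: no complete month in window; falling back to all-day means",
            series.population,
        )
        tmax = float(days["daily_max"].mean())
        tmin = float(days["daily_min"].mean())
        return MicroSummary(tmax, tmin, tmax - tmin, dr, None, None, False)
    # idxmax/idxmin return the first (earliest) period on ties
    warm = full["mean_max"].idxmax()
    cold = full["mean_min"].idxmin()
    tmax = float(full.loc[warm, "mean_max"])
    tmin = float(full.loc[cold, "mean_min"])
    return MicroSummary(tmax, tmin, tmax - tmin, dr, warm.month, cold.month, True)


def macro_summary(
    macro: MacroMonthly, window: PhenologyWindow, min_days: int = 15
) -> MacroSummary:
    """Window extremes from monthly macroclimate values.

    A calendar month is included when at least ``min_days`` of it fall in
    the window; TMAX/TMIN are the extremes over included months.
    """
    months = window.months_included(min_days=min_days)
    if not months:
        raise ValueError(
            f"{macro.population}: no calendar month has >= {min_days} days in the window"
        )
    tmaxes = [macro.tmax_c[m] for m in months]
    tmins = [macro.tmin_c[m] for m in months]
    TMAX = float(max(tmaxes))
    TMIN = float(min(tmins))
    SR_monthly = float(np.mean([mx - mn for mx, mn in zip(tmaxes, tmins)]))
    return MacroSummary(TMAX, TMIN, TMAX - TMIN, SR_monthly, tuple(months))


def climate_summary(
    series: LoggerSeries,
    macro: MacroMonthly,
    window: PhenologyWindow,
    min_coverage_hours: float = 20.0,
    min_month_days: int = 20,
    min_macro_days: int = 15,
) -> ClimateSummary:
    """Combine micro and macro summaries for one population."""
    mi = micro_summary(series, window, min_coverage_hours, min_month_days)
    ma = macro_summary(macro, window, min_days=min_macro_days)
    return ClimateSummary(
        population=series.population,
        TMAX=ma.TMAX, TMIN=ma.TMIN, SR=ma.SR_extreme, SR_monthly=ma.SR_monthly,
        tmax=mi.tmax, tmin=mi.tmin, sr=mi.sr, dr=mi.dr,
        window=window,
    )


def summarize_populations(
    loggers: dict[str, LoggerSeries],
    macros: dict[str, MacroMonthly],
    windows: dict[str, PhenologyWindow],
    alias: dict[str, str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """ClimateSummary rows for every population present in all three inputs.

    ``alias`` maps a population to a donor logger series (e.g. a lost
    datalogger replaced by a nearby pond's record); the donor's data are
    used under the target population's window.
    """
    alias = alias or {}
    rows = []
    for pop in windows:
        series = loggers.get(alias.get(pop, pop))
        macro = macros.get(pop)
        if series is None or macro is None:
            logger.warning("population %s skipped: missing logger or macro data", pop)
            continue
        series = LoggerSeries(population=pop, frame=series.frame)
        rows.append(climate_summary(series, macro, windows[pop], **kwargs).as_row())
    if not rows:
        raise ValueError("no population had a complete set of climate inputs")
    return pd.DataFrame(rows).sort_values("population").reset_index(drop=True)
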