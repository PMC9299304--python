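"""Daily site series I/O, calendar conventions, and season windows.

This module owns the conventions every downstream stage relies on:

* a :class:`DailySeries` is a gap-free daily calendar (missing observations are
  explicit NaN, never absent rows);
* winter runs December–February and is labeled by the January year
  (Dec 2001–Feb 2002 -> winter 2002); summer runs July 1–September 30 and is
  labeled by its calendar year;
* the season containing the fire date is excluded from both phases, the
  "post" phase is the first ``n_post`` complete seasons after it, and the
  "pre" phase is the most recent (up to ``n_pre_max``) complete seasons
  before it.
"""

from __future__ import annotations

import calendar
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "SeasonWindow",
    "SeriesValidationError",
    "load_daily_series",
    "write_daily_series",
    "build_season_windows",
    "season_window",
    "write_result_table",
    "read_result_table",
]

REQUIRED_COLUMNS = ("twater", "tair", "precip", "pet")
OPTIONAL_COLUMNS = ("flow",)
#: Lowest physically plausible daily mean water temperature (°C); values below
#: are flagged in the load report but not rejected (supercooling artifacts).
TWATER_PLAUSIBLE_MIN = -1.0


class SeriesValidationError(ValueError):
    """A daily series violates a structural invariant."""


@dataclass
class DailySeries:
    """A calendar-complete daily record for one stream site.

    ``data`` is indexed by a strictly increasing, gap-free daily
    DatetimeIndex with columns ``twater`` (°C), ``tair`` (°C), ``precip``
    (mm), ``pet`` (mm) and optional ``flow`` (m³/s). Missing observations
    are NaN.
    """

    site_id: str
    data: pd.DataFrame
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise SeriesValidationError("data must be indexed by dates")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise SeriesValidationError(f"duplicate date {dup.date()}")
        if not df.index.is_monotonic_increasing:
            raise SeriesValidationError("dates must be strictly increasing")
        if len(df) > 1:
            deltas = np.diff(df.index.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise SeriesValidationError(
                    "calendar gaps must be materialized as missing values"
                )
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SeriesValidationError(f"missing required column {col!r}")
        if "flow" not in df.columns:
            df["flow"] = np.nan
        for col, label in (("precip", "precipitation"), ("pet", "PET"), ("flow", "flow")):
            bad = df.index[df[col] < 0]
            if len(bad):
                row = int(df.index.get_loc(bad[0]))
                raise SeriesValidationError(
                    f"negative {label} at row {row} ({bad[0].date()})"
                )
        n_suspect = int((df["twater"] < TWATER_PLAUSIBLE_MIN).sum())
        if n_suspect:
            self.load_report.setdefault("suspect_twater_days", n_suspect)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def start(self) -> date:
        return self.data.index[0].date()

    @property
    def end(self) -> date:
        return self.data.index[-1].date()

    @property
    def has_flow(self) -> bool:
        return bool(self.data["flow"].notna().any())

    def copy(self) -> "DailySeries":
        return DailySeries(self.site_id, self.data.copy(), dict(self.load_report))

    def window_slice(self, window: "SeasonWindow") -> pd.DataFrame:
        """Rows of ``data`` falling inside a season window (inclusive)."""
        return self.data.loc[str(window.start) : str(window.end)]


@dataclass(frozen=True, order=True)
class SeasonWindow:
    """One winter or summer season with its position relative to the fire."""

    start: date
    end: date
    season: str  # "winter" | "summer"
    season_year: int
    fire_phase: str  # "pre" | "post" | "fire_year_excluded"

    def __post_init__(self) -> None:
        if self.season not in ("winter", "summer"):
            raise ValueError(f"unknown season {self.season!r}")
        if self.fire_phase not in ("pre", "post", "fire_year_excluded"):
            raise ValueError(f"unknown fire_phase {self.fire_phase!r}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end


def season_window(season: str, season_year: int, fire_phase: str = "pre") -> SeasonWindow:
    """Calendar window for a labeled season.

    Winter ``y`` is Dec 1 of ``y-1`` through the end of February of ``y``
    (Feb 29 included in leap years); summer ``y`` is Jul 1–Sep 30 of ``y``.
    """
    if season == "winter":
        start = date(season_year - 1, 12, 1)
        end = date(season_year, 2, calendar.monthrange(season_year, 2)[1])
    elif season == "summer":
        start = date(season_year, 7, 1)
        end = date(season_year, 9, 30)
    else:
        raise ValueError(f"unknown season {season!r}")
    return SeasonWindow(start, end, season, season_year, fire_phase)


def load_daily_series(path, column_map=None, site_id=None) -> DailySeries:
    """Load a delimited daily record, materializing calendar gaps as NaN.

    Parameters
    ----------
    path : path-like
        CSV with a header; requires a ``date`` column (ISO-8601) plus
        ``twater, tair, precip, pet`` and optional ``flow``.
    column_map : dict, optional
        Mapping from the file's column names to the canonical names.
    site_id : str, optional
        Defaults to the file stem.
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        raw = raw.rename(columns=column_map)
    if "date" not in raw.columns:
        raise SeriesValidationError(f"{path}: no 'date' column")
    parsed = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0])
        raise SeriesValidationError(
            f"{path}: unparseable date {raw['date'].iloc[row]!r} at row {row}"
        )
    if parsed.duplicated().any():
        dup = parsed[parsed.duplicated()].iloc[0]
        raise SeriesValidationError(f"{path}: duplicate date {dup.date()}")
    neg = raw.index[raw.get("precip", pd.Series(dtype=float)) < 0]
    if len(neg):
        raise SeriesValidationError(f"{path}: negative precipitation at row {int(neg[0])}")

    df = raw.drop(columns=["date"]).set_index(pd.DatetimeIndex(parsed, name="date"))
    df = df.sort_index()
    for col in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    full = pd.date_range(df.index[0], df.index[-1], freq="D", name="date")
    n_gaps = len(full) - len(df)
    df = df.reindex(full)
    report = {"n_rows_read": len(raw), "n_gap_days_filled": int(n_gaps)}
    return DailySeries(site_id or path.stem, df, report)


def write_daily_series(series: DailySeries, path) -> None:
    """Write a DailySeries as CSV; re-loading reproduces it bit-exactly."""
    out = series.data.copy()
    out.index.name = "date"
    # shortest round-trip float representation keeps re-loads bit-exact
    out.to_csv(path, date_format="%Y-%m-%d", float_format=lambda v: repr(float(v)))


def build_season_windows(
    series: DailySeries,
    fire_date: date,
    n_pre_max: int = 7,
    n_post: int = 3,
) -> list[SeasonWindow]:
    """Label every usable winter/summer season relative to the fire.

    For each season kind, windows wholly inside the record are classified:
    the window containing ``fire_date`` is ``fire_year_excluded``; windows
    ending before the fire are candidates for ``pre`` (the most recent
    ``n_pre_max`` kept); windows starting after it are ``post`` (the first
    ``n_post`` kept). A winter that merely follows a summer fire within the
    same calendar year is the first post season. Raises if fewer than 3
    complete pre or ``n_post`` complete post seasons exist for either kind.
    """
    if isinstance(fire_date, pd.Timestamp):
        fire_date = fire_date.date()
    if n_pre_max < 3:
        raise ValueError("n_pre_max must be at least 3")
    first, last = series.start, series.end
    out: list[SeasonWindow] = []
    for season in ("winter", "summer"):
        pre, post, excluded = [], [], []
        for year in range(first.year, last.year + 2):
            win = season_window(season, year)
            if win.start < first or win.end > last:
                continue  # incomplete at the record edge
            if win.contains(fire_date):
                excluded.append(dataclasses.replace(win, fire_phase="fire_year_excluded"))
            elif win.end < fire_date:
                pre.append(win)
            elif win.start > fire_date:
                post.append(dataclasses.replace(win, fire_phase="post"))
        if len(pre) < 3:
            raise ValueError(
                f"insufficient pre-fire record: {len(pre)} complete {season} "
                f"season(s) before {fire_date}, need >= 3"
            )
        if len(post) < n_post:
            raise ValueError(
                f"insufficient post-fire record: {len(post)} complete {season} "
                f"season(s) after {fire_date}, need >= {n_post}"
            )
        out.extend(pre[-n_pre_max:])
        out.extend(excluded)
        out.extend(post[:n_post])
    out.sort(key=lambda w: (w.start, w.season))
    return out


# ---------------------------------------------------------------------------
# Result tables


def _result_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result
    if hasattr(result, "to_frame"):
        return result.to_frame()
    if isinstance(result, (list, tuple)) and result and hasattr(result[0], "to_frame"):
        return pd.concat([r.to_frame() for r in result], ignore_index=True)
    raise TypeError(f"cannot tabulate result of type {type(result).__name__}")


def write_result_table(result, path, metadata: dict | None = None) -> None:
    """Write a result as CSV plus a JSON key-value sidecar (``<path>.meta.json``).

    The sidecar records the package version, the result type, and any caller
    metadata (seed, configuration hash, interpretive flags). Values round-trip
    at full float precision.
    """
    from firestream import __version__

    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    frame = _result_frame(result)
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    meta = {
        "firestream_version": __version__,
        "result_type": type(result).__name__,
        "n_rows": int(len(frame)),
    }
    meta.update(metadata or {})
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_result_table(path) -> tuple[pd.DataFrame, dict]:
    """Read back a table written by :func:`write_result_table`."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return frame, meta
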