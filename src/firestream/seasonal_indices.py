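"""Seasonal and weekly thermal/weather indices.

MWT is the mean of available daily mean water temperatures over a window; ADD
(accumulated degree-days) is the raw cumulative sum of daily mean water
temperature above 0 °C — sub-zero daily means are *not* truncated by default,
so for a complete window ADD = MWT x n_days exactly. MAT, precipitation totals
and flow means are computed analogously. Each season is also partitioned into
13 consecutive weekly blocks (12 x 7 days plus a remainder week of 6–8 days)
for the air–water regression stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from firestream.timeseries_io import DailySeries, SeasonWindow

__all__ = [
    "INDEX_NAMES",
    "compute_seasonal_indices",
    "compute_weekly_series",
]

INDEX_NAMES = ("MWT", "ADD", "MAT", "PRECIP_TOTAL", "FLOW_MEAN")

# (index name, source column, aggregator)
_INDEX_DEFS = (
    ("MWT", "twater", "mean"),
    ("ADD", "twater", "sum"),
    ("MAT", "tair", "mean"),
    ("PRECIP_TOTAL", "precip", "sum"),
    ("FLOW_MEAN", "flow", "mean"),
)


def _aggregate(values: pd.Series, how: str, floor_at_zero: bool) -> float:
    vals = values.dropna()
    if len(vals) == 0:
        return np.nan
    if how == "sum":
        v = vals.clip(lower=0.0) if floor_at_zero else vals
        return float(v.sum())
    return float(vals.mean())


def compute_seasonal_indices(
    series: DailySeries,
    windows: list[SeasonWindow],
    completeness_min: float = 0.95,
    floor_add_at_zero: bool = False,
) -> pd.DataFrame:
    """One row per (window, index) with value, days used, and completeness.

    Values are masked (NaN) when the fraction of available days falls below
    ``completeness_min``; an empty window yields completeness 0, not an error.
    ``floor_add_at_zero`` truncates sub-zero daily water temperatures in ADD
    (off by default: the definition is the raw cumulative sum).
    """
    if not 0.0 <= completeness_min <= 1.0:
        raise ValueError("completeness_min must be in [0, 1]")
    rows = []
    include_flow = series.has_flow
    for win in windows:
        sub = series.window_slice(win)
        for name, col, how in _INDEX_DEFS:
            if name == "FLOW_MEAN" and not include_flow:
                continue
            floor = floor_add_at_zero and name == "ADD"
            vals = sub[col] if col in sub else pd.Series(dtype=float)
            n_used = int(vals.notna().sum())
            completeness = n_used / win.n_days
            value = (
                _aggregate(vals, how, floor)
                if completeness >= completeness_min and n_used > 0
                else np.nan
            )
            rows.append(
                {
                    "site_id": series.site_id,
                    "season": win.season,
                    "season_year": win.season_year,
                    "fire_phase": win.fire_phase,
                    "index_name": name,
                    "value": value,
                    "n_days_used": n_used,
                    "completeness": completeness,
                }
            )
    return pd.DataFrame(rows)


def _week_lengths(n_days: int, n_weeks: int = 13) -> list[int]:
    """12 full 7-day blocks plus a remainder block covering the rest."""
    if n_days < 7 * (n_weeks - 1):
        raise ValueError(f"season of {n_days} days too short for {n_weeks} weeks")
    return [7] * (n_weeks - 1) + [n_days - 7 * (n_weeks - 1)]


def compute_weekly_series(
    series: DailySeries, windows: list[SeasonWindow]
) -> pd.DataFrame:
    """Weekly aggregates (week 1..13 per season) for the regression stage.

    Weeks run consecutively from the season's first day: 12 blocks of 7 days
    and a final remainder block (6–7 days in winter, 8 in summer). Weekly MWT
    and MAT are means over available days, weekly ADD is the sum; a week with
    any missing water or air temperature is flagged ``complete=False`` and is
    excluded from regression fits.
    """
    rows = []
    for win in windows:
        sub = series.window_slice(win)
        lengths = _week_lengths(win.n_days)
        offset = 0
        for week_index, n_days in enumerate(lengths, start=1):
            block = sub.iloc[offset : offset + n_days]
            offset += n_days
            twater = block["twater"]
            tair = block["tair"]
            complete = bool(
                len(block) == n_days and twater.notna().all() and tair.notna().all()
            )
            rows.append(
                {
                    "site_id": series.site_id,
                    "season": win.season,
                    "season_year": win.season_year,
                    "fire_phase": win.fire_phase,
                    "week_index": week_index,
                    "n_days": n_days,
                    "week_MAT": float(tair.mean()) if tair.notna().any() else np.nan,
                    "week_MWT": float(twater.mean()) if twater.notna().any() else np.nan,
                    "week_ADD": float(twater.sum()) if twater.notna().any() else np.nan,
                    "complete": complete,
                }
            )
    return pd.DataFrame(rows)
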