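"""Preparation of daily count series for causal analysis.

The causal estimators downstream (transfer entropy, partial correlation,
CCM) assume stationary inputs on a common, gapless daily grid.  This
module turns raw dated counts into that form: an additive
seasonal-trend adjustment via locally weighted regression, the one-day
backward shift that re-dates print-media counts to the day the events
were reported on, and the sparsity/concentration screen that decides
whether a metropolitan area carries enough local-crime coverage to be
analyzed at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import MSTL

ROLES = ("MPB", "MLC", "PT", "NT")
PRINT_ROLES = ("MPB", "MLC")

DEFAULT_PERIODS = (7, 30, 365)


@dataclass(frozen=True)
class DailySeries:
    """A contiguous daily count series with a role and area label.

    Roles: MPB (national media coverage of police brutality), MLC
    (per-area media coverage of local crime), PT / NT (per-area positive
    / negative tweet counts).  ``area`` is empty for the national MPB
    series.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    role: str
    area: str = ""

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if len(dates) != len(values):
            raise ValueError("dates and values differ in length")
        if len(dates) == 0:
            return
        if not np.all(np.isfinite(values)):
            raise ValueError("invalid input: non-finite values")
        if np.any(values < 0):
            raise ValueError("invalid input: negative counts")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("dates must be contiguous calendar days")

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **kw) -> "DailySeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class AdjustedSeries:
    """Residuals of an additive trend + multi-seasonal decomposition.

    ``residuals + removed_trend + sum(removed_seasonals.values())``
    reconstructs the input series elementwise.
    """

    dates: pd.DatetimeIndex
    residuals: np.ndarray
    removed_trend: np.ndarray
    removed_seasonals: dict[int, np.ndarray] = field(default_factory=dict)
    role: str = ""
    area: str = ""

    def reconstruct(self) -> np.ndarray:
        out = self.residuals + self.removed_trend
        for comp in self.removed_seasonals.values():
            out = out + comp
        return out

    def __len__(self) -> int:
        return len(self.residuals)


def _next_odd(v: float) -> int:
    w = int(np.ceil(v))
    return w if w % 2 == 1 else w + 1


def decompose_and_adjust(
    series: DailySeries,
    periods: tuple[int, ...] = DEFAULT_PERIODS,
    windows: tuple[int, ...] | None = None,
    trend_window: int | None = None,
) -> AdjustedSeries:
    """Remove trend and the declared seasonal cycles, additively.

    Seasonal-trend decomposition by locally weighted regression (STL),
    iterated over the periods from shortest to longest (MSTL).  The
    default periods 7 / 30 / 365 days stand for the weekly, monthly and
    yearly cycles of media and posting activity.

    Calendar seasonality in these data is stable across cycles, so the
    default seasonal LOESS spans are near-periodic — the next odd
    integer >= 1.5 x the number of available cycles of each period —
    and the trend span covers more than a year (next odd >= 1.5 x 365).
    Short spans would let the seasonal and trend components soak up the
    day-to-day fluctuations that the causal estimators feed on.

    Parameters
    ----------
    series : DailySeries
        Input counts; length must be at least twice the longest period.
    periods : tuple of int
        Season lengths in days.
    windows : tuple of int, optional
        Seasonal LOESS spans (in cycles of the seasonal sub-series),
        one per period, shortest period first.
    trend_window : int, optional
        Trend LOESS span in days.

    Returns
    -------
    AdjustedSeries
        Residuals plus the removed components; the additive
        reconstruction invariant holds to numerical precision.
    """
    periods = tuple(sorted(int(p) for p in periods))
    if any(p < 2 for p in periods):
        raise ValueError("seasonal periods must be >= 2 days")
    if len(series) < 2 * max(periods):
        raise ValueError(
            f"insufficient span: need >= {2 * max(periods)} days, got {len(series)}"
        )
    if windows is None:
        windows = tuple(_next_odd(1.5 * len(series) / p) for p in periods)
    if trend_window is None:
        trend_window = _next_odd(1.5 * max(365, max(periods)))
    res = MSTL(
        series.values,
        periods=periods,
        windows=windows,
        stl_kwargs={"trend": trend_window},
    ).fit()
    seasonal = np.atleast_2d(np.asarray(res.seasonal).T)
    removed = {p: seasonal[i].astype(float) for i, p in enumerate(periods)}
    return AdjustedSeries(
        dates=series.dates,
        residuals=np.asarray(res.resid, dtype=float),
        removed_trend=np.asarray(res.trend, dtype=float),
        removed_seasonals=removed,
        role=series.role,
        area=series.area,
    )


def align_print_media(series: DailySeries) -> DailySeries:
    """Shift a print-media series backward by one day.

    A count printed on day ``d`` describes events of day ``d - 1``, so
    the value reported on ``d`` is reassigned to ``d - 1`` and the final
    day is dropped (nothing is printed about it yet).
    """
    if series.role not in PRINT_ROLES:
        raise ValueError(
            f"role mismatch: backward shift applies to {PRINT_ROLES}, got {series.role!r}"
        )
    if len(series) == 0:
        raise ValueError("empty input")
    return series.replace(dates=series.dates[:-1], values=series.values[1:])


@dataclass(frozen=True)
class ScreenDecision:
    included: bool
    reason: str
    mean_per_day: float
    max_window_fraction: float


def screen_area(
    mlc: DailySeries,
    min_daily_mean: float = 0.8,
    concentration_fraction: float = 1.0 / 3.0,
    concentration_window_days: int = 2,
) -> ScreenDecision:
    """Decide whether an area's local-crime coverage supports analysis.

    Excludes areas whose coverage is too sparse (mean below
    ``min_daily_mean`` counts/day) or too concentrated (any sliding
    window of ``concentration_window_days`` holding more than
    ``concentration_fraction`` of the series total) for symbolization
    and detrending to be meaningful.
    """
    values = mlc.values
    total = values.sum()
    if total == 0:
        return ScreenDecision(False, "degenerate", 0.0, 0.0)
    mean = float(values.mean())
    w = int(concentration_window_days)
    if len(values) >= w:
        window_sums = np.convolve(values, np.ones(w), mode="valid")
        max_frac = float(window_sums.max() / total)
    else:
        max_frac = 1.0
    if mean < min_daily_mean:
        return ScreenDecision(False, "sparse", mean, max_frac)
    if max_frac > concentration_fraction:
        return ScreenDecision(False, "concentrated", mean, max_frac)
    return ScreenDecision(True, "included", mean, max_frac)


# ---------------------------------------------------------------------------
# long-format CSV I/O: columns date (ISO-8601), area, role, value
# ---------------------------------------------------------------------------

def read_panel_csv(path) -> list[DailySeries]:
    """Read a long-format panel CSV into DailySeries, one per (area, role)."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "area", "role", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    df["area"] = df["area"].fillna("")
    out = []
    for (area, role), grp in df.groupby(["area", "role"], sort=True):
        grp = grp.sort_values("date")
        out.append(
            DailySeries(
                dates=pd.DatetimeIndex(grp["date"]),
                values=grp["value"].to_numpy(dtype=float),
                role=str(role),
                area=str(area),
            )
        )
    return out


def write_panel_csv(series_list: list[DailySeries], path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "date": s.dates.strftime("%Y-%m-%d"),
                    "area": s.area,
                    "role": s.role,
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
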