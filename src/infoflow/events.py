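"""Minute-resolution event-response analysis.

Around each media event (a newspaper post), the average response rate
(tweets/minute) is computed over a pre window and a post window of
equal semi-width; a one-tailed Wilcoxon signed-rank test across events
asks whether the post-event rate is systematically greater.  The test
is swept over a grid of semi-widths to trace the time scale of the
public's response.

Internally time is an integer minute grid; CSV readers convert
timestamped data to that grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EventStream:
    """Event times (integer minutes from span start) within [0, span)."""

    event_times: np.ndarray
    span_minutes: int

    def __post_init__(self):
        t = np.sort(np.asarray(self.event_times, dtype=np.int64))
        object.__setattr__(self, "event_times", t)
        if len(t) and (t[0] < 0 or t[-1] >= self.span_minutes):
            raise ValueError("event times must lie within the observation span")

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass(frozen=True)
class EventStudyResult:
    semiwidths: np.ndarray              # minutes
    p_values: np.ndarray                # one-tailed, one per semi-width
    pre_means: list[np.ndarray]         # per-semi-width, per retained event
    post_means: list[np.ndarray]
    n_events: np.ndarray                # retained events per semi-width
    area: str = ""


DEFAULT_SEMIWIDTH_GRID = tuple(range(30, 721, 30))


def event_window_rates(events: EventStream, minutely_counts, semiwidth: int):
    """Paired (pre, post) mean rates per event for one semi-width.

    Pre covers the ``semiwidth`` minutes strictly before the event, post
    the ``semiwidth`` minutes strictly after; the event minute belongs
    to neither.  Events whose window exits the observation span are
    dropped.  Returns ``(pre_means, post_means, n_dropped)``.
    """
    counts = np.asarray(minutely_counts, dtype=float)
    if len(counts) != events.span_minutes:
        raise ValueError("minutely counts must cover the full observation span")
    s = int(semiwidth)
    if s < 1:
        raise ValueError("semiwidth must be >= 1 minute")
    t = events.event_times
    keep = (t - s >= 0) & (t + s < len(counts))
    retained = t[keep]
    if len(retained) == 0:
        raise ValueError("no analyzable events")
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    pre = (csum[retained] - csum[retained - s]) / s
    post = (csum[retained + 1 + s] - csum[retained + 1]) / s
    return pre, post, int(len(t) - len(retained))


def signed_rank_event_test(pre, post) -> float:
    """One-tailed Wilcoxon signed-rank p for post-rate > pre-rate.

    Zero differences are dropped; the exact null distribution is used
    for small samples without ties, the tie-corrected normal
    approximation otherwise (always for n > 25).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    d = post - pre
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; test is uninformative")
        return 1.0
    if len(nz) < 6:
        warnings.warn("fewer than 6 non-zero differences; p-value is coarse")
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(post, pre, alternative="greater",
                         zero_method="wilcox", method=method)
    return float(res.pvalue)


def sweep_windows(
    events: EventStream,
    minutely_counts,
    semiwidth_grid=DEFAULT_SEMIWIDTH_GRID,
    area: str = "",
) -> EventStudyResult:
    """Run the paired signed-rank test over a grid of semi-widths."""
    grid = np.asarray(sorted(int(s) for s in semiwidth_grid))
    ps, pres, posts, ns = [], [], [], []
    for s in grid:
        pre, post, _ = event_window_rates(events, minutely_counts, s)
        ps.append(signed_rank_event_test(pre, post))
        pres.append(pre)
        posts.append(post)
        ns.append(len(pre))
    return EventStudyResult(
        semiwidths=grid,
        p_values=np.asarray(ps),
        pre_means=pres,
        post_means=posts,
        n_events=np.asarray(ns),
        area=area,
    )


def count_significant_areas(results: dict[str, EventStudyResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-semi-width count of areas whose one-tailed p falls below alpha."""
    grids = [tuple(r.semiwidths) for r in results.values()]
    if len(set(grids)) != 1:
        raise ValueError("all areas must share the same semi-width grid")
    grid = np.asarray(grids[0])
    mat = np.vstack([r.p_values for r in results.values()])
    return pd.DataFrame(
        {"semiwidth_min": grid, "n_significant": (mat < alpha).sum(axis=0),
         "n_areas": len(results)}
    )


# ---------------------------------------------------------------------------
# CSV I/O on timestamped data
# ---------------------------------------------------------------------------

def read_event_csv(path, span_start, span_end) -> EventStream:
    """Events CSV with a ``timestamp`` column -> integer-minute stream."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    start = pd.Timestamp(span_start)
    span = int((pd.Timestamp(span_end) - start).total_seconds() // 60) + 1
    mins = ((df["timestamp"] - start).dt.total_seconds() // 60).astype(int)
    return EventStream(event_times=mins.to_numpy(), span_minutes=span)


def read_minutely_counts_csv(path, span_start, span_end, area=None) -> np.ndarray:
    """Minutely counts CSV (timestamp, area, count) -> dense count vector."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if area is not None:
        df = df[df["area"] == area]
    start = pd.Timestamp(span_start)
    span = int((pd.Timestamp(span_end) - start).total_seconds() // 60) + 1
    out = np.zeros(span)
    mins = ((df["timestamp"] - start).dt.total_seconds() // 60).astype(int)
    np.add.at(out, mins.to_numpy(), df["count"].to_numpy(dtype=float))
    return out
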