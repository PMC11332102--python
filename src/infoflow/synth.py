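"""Synthetic data with known causal ground truth.

The study's raw data (tweets) are not shareable, so every pipeline
stage is exercised on generated data whose causal structure is known by
construction: coupled 3-state Markov chains in the standard confounding
motifs (direct link, common driver, cascade), seasonal count series for
the adjustment stage, coupled logistic maps for CCM, and a
baseline-plus-excitation point process for the event study.  Every
generator takes an explicit seed and returns its ground truth alongside
the data; recovery tests must never re-derive truth from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventStream
from .preprocess import DailySeries

MOTIFS = ("direct", "common_driver", "cascade", "independent")

#: Poisson emission rates per hidden state (low/medium/high).  Wide
#: separation keeps the hidden state recoverable after tertile binning
#: of seasonally adjusted counts, mimicking count series whose level is
#: informative about the underlying activity regime.
DEFAULT_STATE_RATES = (5.0, 15.0, 30.0)


@dataclass(frozen=True)
class MotifSpec:
    """Specification of a coupled-chain motif with known adjacency.

    ``coupling`` is the probability that the driven chain copies its
    driver's state instead of drawing uniformly; 0 gives mutual
    independence, 1 a deterministic copy.
    """

    motif: str
    coupling: float
    length: int
    seed: int
    alphabet_size: int = 3
    emission: str = "symbolic"          # or "poisson"
    state_rates: tuple[float, ...] = DEFAULT_STATE_RATES

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")

    @property
    def true_links(self) -> frozenset[tuple[str, str]]:
        """Directed ground-truth adjacency over (X, Y, Z)."""
        return frozenset(
            {
                "direct": {("Y", "X")},
                "common_driver": {("Z", "X"), ("Z", "Y")},
                "cascade": {("Y", "Z"), ("Z", "X")},
                "independent": set(),
            }[self.motif]
        )


def _copy_or_uniform(rng, driver: np.ndarray, coupling: float, s: int) -> np.ndarray:
    noise = rng.integers(0, s, size=len(driver))
    take = rng.random(len(driver)) < coupling
    return np.where(take, driver, noise)


def gen_coupled_markov(spec: MotifSpec) -> dict:
    """Generate aligned series (X, Y, Z) under the motif's adjacency.

    Lag-1 couplings: direct Y_t -> X_{t+1}; cascade Y -> Z -> X with
    the middle link contemporaneous (Z_t copies Y_t) and Z_t -> X_{t+1}.
    The common-driver motif makes Y copy Z contemporaneously while X
    copies Z with lag one, so the spurious Y -> X dependence that
    conditioning must remove actually exists at lag 1 (a memoryless
    driver copied with equal lags into both chains would leave Y_t and
    X_{t+1} independent).

    Returns ``{"X", "Y", "Z", "spec"}``; with ``emission="poisson"``
    the hidden states additionally drive Poisson counts returned as
    ``X_counts`` etc.
    """
    rng = np.random.default_rng(spec.seed)
    n, s, c = spec.length, spec.alphabet_size, spec.coupling
    if spec.motif == "direct":
        y = rng.integers(0, s, size=n)
        z = rng.integers(0, s, size=n)
        x = np.empty(n, dtype=np.int64)
        x[0] = rng.integers(0, s)
        x[1:] = _copy_or_uniform(rng, y[:-1], c, s)
    elif spec.motif == "common_driver":
        z = rng.integers(0, s, size=n)
        y = _copy_or_uniform(rng, z, c, s)
        x = np.empty(n, dtype=np.int64)
        x[0] = rng.integers(0, s)
        x[1:] = _copy_or_uniform(rng, z[:-1], c, s)
    elif spec.motif == "cascade":
        y = rng.integers(0, s, size=n)
        z = _copy_or_uniform(rng, y, c, s)
        x = np.empty(n, dtype=np.int64)
        x[0] = rng.integers(0, s)
        x[1:] = _copy_or_uniform(rng, z[:-1], c, s)
    else:  # independent
        x = rng.integers(0, s, size=n)
        y = rng.integers(0, s, size=n)
        z = rng.integers(0, s, size=n)
    out = {"X": x, "Y": y, "Z": z, "spec": spec}
    if spec.emission == "poisson":
        rates = np.asarray(spec.state_rates, float)
        if len(rates) != s:
            raise ValueError("one emission rate per hidden state required")
        for name in ("X", "Y", "Z"):
            out[f"{name}_counts"] = rng.poisson(rates[out[name]]).astype(float)
    return out


def gen_seasonal_counts(
    trend_slope: float = 0.002,
    weekly_amp: float = 3.0,
    yearly_amp: float = 5.0,
    noise_sd: float = 2.0,
    n_days: int = 1095,
    seed: int = 0,
    base_level: float = 20.0,
    start: str = "2010-10-01",
    role: str = "NT",
    area: str = "synthetic",
) -> tuple[DailySeries, dict]:
    """Daily counts = base + linear trend + weekly + yearly cycle + noise.

    Values are truncated at zero after summation (the returned ground
    truth stores the pre-truncation components).  Returns
    ``(DailySeries, truth)`` with truth keys ``trend``, ``weekly``,
    ``yearly``, ``noise``.
    """
    if n_days < 730:
        raise ValueError("n_days must be >= 730 (two yearly cycles)")
    if weekly_amp < 0 or yearly_amp < 0 or noise_sd < 0:
        raise ValueError("amplitudes and noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)
    trend = base_level + trend_slope * t
    weekly = weekly_amp * np.sin(2 * np.pi * t / 7.0)
    yearly = yearly_amp * np.sin(2 * np.pi * t / 365.0)
    noise = rng.normal(0.0, noise_sd, size=n_days)
    values = np.clip(trend + weekly + yearly + noise, 0.0, None)
    series = DailySeries(
        dates=pd.date_range(start, periods=n_days, freq="D"),
        values=values,
        role=role,
        area=area,
    )
    truth = {"trend": trend, "weekly": weekly, "yearly": yearly, "noise": noise}
    return series, truth


def gen_logistic_pair(
    r_x: float = 3.8,
    r_y: float = 3.5,
    beta_xy: float = 0.02,
    beta_yx: float = 0.0,
    n: int = 1000,
    seed: int = 0,
    burn_in: int = 300,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Coupled logistic maps, the standard CCM benchmark.

        x_{t+1} = x_t (r_x - r_x x_t - beta_xy y_t)
        y_{t+1} = y_t (r_y - r_y y_t - beta_yx x_t)

    ``beta_xy > 0`` means y influences x, i.e. the ground-truth causal
    direction is y -> x.  Trajectories leaving (0, 1) raise
    "divergent parameters".  Returns ``(x, y, truth)``.
    """
    if burn_in < 100:
        raise ValueError("burn_in must be >= 100")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    x = np.empty(total)
    y = np.empty(total)
    x[0] = rng.uniform(0.2, 0.8)
    y[0] = rng.uniform(0.2, 0.8)
    for t in range(total - 1):
        x[t + 1] = x[t] * (r_x - r_x * x[t] - beta_xy * y[t])
        y[t + 1] = y[t] * (r_y - r_y * y[t] - beta_yx * x[t])
        if not (0.0 < x[t + 1] < 1.0 and 0.0 < y[t + 1] < 1.0):
            raise ValueError("divergent parameters: trajectory left (0, 1)")
    truth = {
        "y_drives_x": beta_xy > 0,
        "x_drives_y": beta_yx > 0,
    }
    return x[burn_in:], y[burn_in:], truth


def gen_event_study(
    base_rate: float = 1.0,
    excitation_height: float = 0.0,
    excitation_minutes: int = 120,
    n_events: int = 100,
    span_minutes: int = 20160,
    seed: int = 0,
    spacing: str = "uniform",
) -> tuple[EventStream, np.ndarray, dict]:
    """Events plus a Poisson minutely response with optional excitation.

    The response rate is ``base_rate`` everywhere, raised by
    ``excitation_height`` for ``excitation_minutes`` minutes after each
    event (windows may overlap; rates add).  The default span is the
    study's two-week observation window (14 x 1440 minutes).  Returns
    ``(EventStream, counts, truth)``.
    """
    if base_rate < 0 or excitation_height < 0:
        raise ValueError("rates must be non-negative")
    if span_minutes < 4 * n_events:
        raise ValueError("span too short for the requested number of events")
    rng = np.random.default_rng(seed)
    if spacing == "uniform":
        times = np.sort(rng.choice(span_minutes, size=n_events, replace=False))
    elif spacing == "fixed":
        times = np.linspace(0, span_minutes - 1, n_events).astype(np.int64)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    rate = np.full(span_minutes, float(base_rate))
    for e in times:
        hi = min(span_minutes, e + 1 + excitation_minutes)
        rate[e + 1 : hi] += excitation_height
    counts = rng.poisson(rate).astype(float)
    events = EventStream(event_times=times, span_minutes=span_minutes)
    truth = {
        "base_rate": base_rate,
        "excitation_height": excitation_height,
        "excitation_minutes": excitation_minutes,
        "rate": rate,
    }
    return events, counts, truth


# ---------------------------------------------------------------------------
# multi-area panel emulating the study layout
# ---------------------------------------------------------------------------

def gen_panel(
    n_areas: int = 18,
    n_days: int = 3745,
    coupling_mpb_nt: float = 0.0,
    seed: int = 0,
    state_rates: tuple[float, float, float] = DEFAULT_STATE_RATES,
    weekly_amp: float = 2.0,
    yearly_amp: float = 3.0,
    trend_slope: float = 0.001,
    start: str = "2010-10-01",
) -> tuple[list[DailySeries], dict]:
    """A study-shaped panel: one national MPB series, per-area MLC/PT/NT.

    A shared national hidden 3-state chain U drives MPB; with
    ``coupling_mpb_nt > 0`` each area's NT chain copies U with lag one
    (NT_{t+1} <- U_t) at that probability, while MLC and PT stay
    independent.  Hidden states emit Poisson counts with
    ``state_rates``, plus weekly/yearly cycles and a mild trend so the
    adjustment stage does real work.  Print-media series (MPB, MLC) are
    dated one day *after* the state that drives them, matching the
    print convention the pipeline's backward shift undoes.

    Returns ``(series_list, truth)``; truth records the hidden chains
    and the coupled-link adjacency.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)
    rates = np.asarray(state_rates, float)
    dates = pd.date_range(start, periods=n_days, freq="D")

    def emit(states):
        # per-series seasonal phases: a phase shared across series would
        # itself be a common driver and corrupt the declared ground truth
        pw, py = rng.uniform(0, 2 * np.pi, size=2)
        season = (
            weekly_amp * np.sin(2 * np.pi * t / 7.0 + pw)
            + yearly_amp * np.sin(2 * np.pi * t / 365.0 + py)
            + trend_slope * t
        )
        return np.clip(rng.poisson(rates[states]) + season, 0.0, None)

    # h[t] = national hidden state on day t; MPB printed on day d reports
    # h[d-1] (h0 pads the first print day), so the backward shift recovers h
    h = rng.integers(0, 3, size=n_days)
    h0 = rng.integers(0, 3)
    mpb_states = np.concatenate([[h0], h[:-1]])
    mpb = DailySeries(dates=dates, values=emit(mpb_states), role="MPB", area="")
    series = [mpb]
    truth = {"hidden_mpb": h, "areas": {}, "coupling_mpb_nt": coupling_mpb_nt,
             "true_links": {("MPB", "NT")} if coupling_mpb_nt > 0 else set()}
    for a in range(n_areas):
        area = f"area{a:02d}"
        nt_states = np.empty(n_days, dtype=np.int64)
        nt_states[0] = rng.integers(0, 3)
        # NT_{t+1} copies the national state of day t
        nt_states[1:] = _copy_or_uniform(rng, h[: n_days - 1], coupling_mpb_nt, 3)
        mlc_states = rng.integers(0, 3, size=n_days)
        pt_states = rng.integers(0, 3, size=n_days)
        series.append(DailySeries(dates=dates, values=emit(mlc_states), role="MLC", area=area))
        series.append(DailySeries(dates=dates, values=emit(pt_states), role="PT", area=area))
        series.append(DailySeries(dates=dates, values=emit(nt_states), role="NT", area=area))
        truth["areas"][area] = {"nt": nt_states, "mlc": mlc_states, "pt": pt_states}
    return series, truth
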