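"""Convergent cross mapping: delay embedding, simplex projection, convergence.

For coupled dynamical systems, if series x drives series y then the
delay embedding (shadow manifold) of y contains the information needed
to reconstruct x.  The reconstruction at each embedding point is an
exponentially distance-weighted average of the target values at the
times of the point's nearest library neighbors (simplex projection),
and the reconstruction skill is the Pearson correlation between the
reconstruction and the truth.  Causality is read off the *convergence*
of skill as the library grows denser: a true direction converges
upward, a non-coupled direction stays flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DelayEmbedding:
    """Delay vectors ``[y_t, y_{t-tau}, ..., y_{t-(E-1)tau}]``."""

    points: np.ndarray      # (m, E)
    E: int
    tau: int
    times: np.ndarray       # time index t of each point in the source series
    source_length: int

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CCMCurve:
    library_lengths: np.ndarray
    skills: np.ndarray          # (n_lengths, replicates)
    replicates: int
    E: int
    tau: int
    n_neighbors: int
    direction: str = ""

    @property
    def mean_skill(self) -> np.ndarray:
        return np.nanmean(self.skills, axis=1)

    @property
    def sd_skill(self) -> np.ndarray:
        return np.nanstd(self.skills, axis=1)


def delay_embed(series, E: int, tau: int = 1) -> DelayEmbedding:
    """Embed a series with dimension ``E`` and delay ``tau``.

    Produces ``N - (E-1)*tau`` points; the point at time t stacks the
    current value first, then increasingly lagged ones.
    """
    y = np.asarray(series, dtype=float)
    N = len(y)
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    offset = (E - 1) * tau
    if N <= offset:
        raise ValueError("insufficient length for embedding")
    times = np.arange(offset, N)
    points = np.column_stack([y[times - j * tau] for j in range(E)])
    return DelayEmbedding(points=points, E=E, tau=tau, times=times, source_length=N)


def _simplex_weights(d: np.ndarray) -> np.ndarray:
    """Exponential distance weights; exact-match collapse when d1 == 0."""
    d1 = d[0]
    if d1 == 0.0:
        w = (d == 0.0).astype(float)
    else:
        w = np.exp(-d / d1)
    return w / w.sum()


def simplex_cross_map(
    target_values,
    embedding: DelayEmbedding,
    n_neighbors: int | None = None,
    library: np.ndarray | None = None,
    exclude_self: bool = True,
    prediction_horizon: int = 0,
):
    """Reconstruct a target series from the embedding of another series.

    For every embedding point, find its ``n_neighbors`` nearest library
    points (Euclidean distance, ties broken by earlier library index),
    weight them by ``w_i = exp(-d_i/d_1) / sum_j exp(-d_j/d_1)`` and
    average the target values time-aligned with the neighbors
    (``prediction_horizon`` steps ahead; 0 for cross mapping, 1 for
    self-prediction embedding selection).

    Returns ``(reconstruction, skill, times)`` where skill is the
    Pearson correlation between reconstruction and truth.
    """
    target = np.asarray(target_values, dtype=float)
    pts = embedding.points
    times = embedding.times
    lib = np.arange(len(pts)) if library is None else np.asarray(library)
    # library points must have a valid target value at t + horizon
    lib = lib[times[lib] + prediction_horizon < len(target)]
    k = embedding.E + 1 if n_neighbors is None else int(n_neighbors)
    if len(lib) < k + (1 if exclude_self else 0):
        raise ValueError("library too small")
    pred_mask = times + prediction_horizon < len(target)
    pred_idx = np.flatnonzero(pred_mask)

    lib_pts = pts[lib]
    recon = np.full(len(pred_idx), np.nan)
    lib_set = set(lib.tolist()) if exclude_self else None
    # full pairwise distances: fine at the few-thousand-point scale used here
    d2 = (
        np.sum(pts[pred_idx] ** 2, axis=1)[:, None]
        + np.sum(lib_pts**2, axis=1)[None, :]
        - 2.0 * pts[pred_idx] @ lib_pts.T
    )
    np.maximum(d2, 0.0, out=d2)
    for row, i in enumerate(pred_idx):
        d = np.sqrt(d2[row])
        if exclude_self and i in lib_set:
            d = d.copy()
            d[np.searchsorted(lib, i)] = np.inf
        order = np.lexsort((lib, d))[:k]
        w = _simplex_weights(d[order])
        recon[row] = w @ target[times[lib[order]] + prediction_horizon]

    truth = target[times[pred_idx] + prediction_horizon]
    if np.std(recon) == 0 or np.std(truth) == 0:
        skill = np.nan
    else:
        skill = float(np.corrcoef(recon, truth)[0, 1])
    return recon, skill, times[pred_idx]


def ccm_convergence(
    x,
    y,
    E: int,
    tau: int = 1,
    library_lengths=(),
    replicates: int = 30,
    seed: int = 0,
    n_neighbors: int | None = None,
) -> dict[str, CCMCurve]:
    """Cross-map skill in both directions as a function of library length.

    For each library length L and replicate, a random contiguous block
    of L embedding points serves as the library (contiguity preserves
    the temporal adjacency the embedding relies on).  Key ``"x->y"``
    holds the skill of reconstructing x from the embedding of y —
    evidence that x drives y — and ``"y->x"`` the reverse.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lengths = np.asarray(sorted(int(v) for v in library_lengths))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    emb_x = delay_embed(x, E, tau)
    emb_y = delay_embed(y, E, tau)
    if lengths.max() > min(len(emb_x), len(emb_y)):
        raise ValueError("library exceeds data")
    rng = np.random.default_rng(seed)
    k = E + 1 if n_neighbors is None else n_neighbors
    out = {}
    for name, emb, target in (("x->y", emb_y, x), ("y->x", emb_x, y)):
        skills = np.full((len(lengths), replicates), np.nan)
        for li, L in enumerate(lengths):
            starts = rng.integers(0, len(emb) - L + 1, size=replicates)
            for r, s0 in enumerate(starts):
                lib = np.arange(s0, s0 + L)
                _, skill, _ = simplex_cross_map(
                    target, emb, n_neighbors=k, library=lib, exclude_self=True
                )
                skills[li, r] = skill
        out[name] = CCMCurve(
            library_lengths=lengths, skills=skills, replicates=replicates,
            E=E, tau=tau, n_neighbors=k, direction=name,
        )
    return out


def select_embedding(series, E_range=range(1, 9), tau: int = 1,
                     parsimony_tol: float = 0.01) -> int:
    """Pick the embedding dimension that best unfolds the attractor.

    Sweeps E over ``E_range`` and scores each by one-step-ahead
    self-prediction skill with simplex projection on leave-one-out
    libraries.  Among dimensions within ``parsimony_tol`` of the best
    skill the smallest E wins: once the attractor is unfolded, extra
    dimensions add noise-prone degrees of freedom without predictive
    gain.
    """
    E_range = list(E_range)
    if not E_range:
        raise ValueError("E_range must be non-empty")
    y = np.asarray(series, float)
    if np.std(y) == 0:
        raise ValueError("degenerate series")
    skills = []
    for E in E_range:
        emb = delay_embed(y, E, tau)
        _, skill, _ = simplex_cross_map(
            y, emb, n_neighbors=E + 1, exclude_self=True, prediction_horizon=1
        )
        skills.append(-np.inf if np.isnan(skill) else skill)
    best_skill = max(skills)
    if best_skill < 0.1:
        warnings.warn("low skill: self-prediction is weak for every E")
    for E, skill in zip(E_range, skills):
        if skill >= best_skill - parsimony_tol:
            return E
    return E_range[int(np.argmax(skills))]


def curve_to_rows(curve: CCMCurve) -> list[dict]:
    """Flatten a CCMCurve to CSV-ready rows (length, replicate, skill)."""
    rows = []
    for li, L in enumerate(curve.library_lengths):
        for r in range(curve.replicates):
            rows.append(
                {
                    "direction": curve.direction,
                    "library_length": int(L),
                    "replicate": r,
                    "skill": float(curve.skills[li, r]),
                }
            )
    return rows
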