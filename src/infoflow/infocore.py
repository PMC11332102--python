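"""Symbolization and plug-in information measures.

Continuous daily residuals are mapped to a small alphabet by rank-based
quantile binning (tertiles by default: low / medium / high), and all
entropies are plug-in estimates from empirical symbol frequencies in
bits (log base 2).  Conditional transfer entropy from a source Y to a
target X given conditioners Z_1..Z_m with history length k is the
entropy difference

    TE_{Y->X|Z} = H(X_{t+1} | X-past, Z-past) - H(X_{t+1} | X-past, Y-past, Z-past),

which on the same counts equals the conditional mutual information
I(X_{t+1}; Y-past | X-past, Z-past).  No bias correction is applied:
the small-sample bias of the plug-in estimator is absorbed by the
surrogate null distribution built in :mod:`infoflow.surrogates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class SymbolicSeries:
    """Integer symbols in ``0..alphabet_size-1`` plus the cut points used."""

    symbols: np.ndarray
    alphabet_size: int
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        sym = np.asarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", sym)
        if len(sym) and (sym.min() < 0 or sym.max() >= self.alphabet_size):
            raise ValueError("symbols outside alphabet range")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class EntropyEstimate:
    value: float            # bits
    support_size: int       # distinct joint states observed
    n: int                  # tuples used


@dataclass(frozen=True)
class CTEEstimate:
    value: float            # bits
    k: int                  # history length (time steps of the past)
    n_transitions: int
    source_role: str = ""
    target_role: str = ""
    conditioner_roles: tuple[str, ...] = ()


def symbolize_tertiles(
    values,
    s: int = 3,
    tie_rule: str = "stable-rank",
) -> SymbolicSeries:
    """Bin a real series into ``s`` near-equal quantile groups by rank.

    ``tie_rule='stable-rank'`` breaks ties by time index (stable sort),
    yielding balanced bins even for zero-inflated counts; occupancies
    then differ by at most one.  ``tie_rule='value-edge'`` cuts at the
    empirical quantile values instead, so tied boundary values all land
    in one bin (useful as a sensitivity check, unbalanced under ties).
    Bin 0 is low, bin ``s - 1`` is high.
    """
    values = np.asarray(values, dtype=float)
    if s < 2:
        raise ValueError("alphabet size must be >= 2")
    n = len(values)
    if n < s or len(np.unique(values)) < 2:
        raise ValueError("degenerate quantiles: too few distinct values")
    qs = np.linspace(0, 1, s + 1)
    edges = np.quantile(values, qs[1:-1])
    if tie_rule == "stable-rank":
        order = np.argsort(values, kind="stable")
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        symbols = (ranks * s) // n
    elif tie_rule == "value-edge":
        symbols = np.searchsorted(edges, values, side="right")
        if len(np.unique(symbols)) < 2:
            raise ValueError("degenerate quantiles: ties collapse all bins")
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return SymbolicSeries(symbols=symbols, alphabet_size=s, bin_edges=edges)


def _entropy_bits_from_counts(counts: np.ndarray, n: int) -> float:
    # H = log2(n) - (1/n) sum c*log2(c), with 0*log 0 := 0
    return float(np.log2(n) - xlogy(counts, counts).sum() / (_LN2 * n))


def entropy(joint_tuples) -> EntropyEstimate:
    """Plug-in joint entropy of a sequence of symbol tuples, in bits.

    Accepts a 1-D sequence of symbols or a 2-D array of shape
    ``(n, d)`` whose rows are joint states.
    """
    arr = np.asarray(joint_tuples)
    if arr.size == 0:
        raise ValueError("no data")
    if arr.ndim == 1:
        arr = arr[:, None]
    _, counts = np.unique(arr, axis=0, return_counts=True)
    n = arr.shape[0]
    return EntropyEstimate(
        value=_entropy_bits_from_counts(counts, n),
        support_size=len(counts),
        n=n,
    )


def conditional_entropy(joint_xy, joint_y) -> float:
    """H(X|Y) = H(X,Y) - H(Y) on the same tuple counts, in bits."""
    return entropy(joint_xy).value - entropy(joint_y).value


def _as_symbols(series) -> tuple[np.ndarray, int]:
    if isinstance(series, SymbolicSeries):
        return series.symbols, series.alphabet_size
    arr = np.asarray(series, dtype=np.int64)
    return arr, int(arr.max()) + 1 if len(arr) else 1


def _history_columns(x: np.ndarray, k: int, n: int) -> list[np.ndarray]:
    """Columns [v_t, v_{t-1}, .., v_{t-k+1}] aligned with targets x[k:]."""
    return [x[k - 1 - j : n - 1 - j] for j in range(k)]


def encode_columns(columns: list[np.ndarray], bases: list[int]) -> tuple[np.ndarray, int]:
    """Mixed-radix encoding of aligned symbol columns into integer codes."""
    code = np.zeros(len(columns[0]), dtype=np.int64)
    size = 1
    for col, b in zip(columns, bases):
        code = code * b + col
        size *= b
    return code, size


def build_te_states(target, source, conditioners=(), k: int = 1,
                    condition_history: bool = True):
    """Aligned state columns for the transfer-entropy estimator.

    Returns ``(x_future, x_past, y_past, z_past, alphabets)`` where each
    past block is a list of lag columns (lag 1..k for the target; lag
    1..k — or lag 1 only when ``condition_history`` is false — for the
    source and conditioners), all aligned with ``x_future = x[k:]``.
    """
    x, sx = _as_symbols(target)
    y, sy = _as_symbols(source)
    zs = [_as_symbols(z) for z in conditioners]
    n = len(x)
    if len(y) != n or any(len(z) != n for z, _ in zs):
        raise ValueError("unaligned series: equal lengths required")
    if k < 1:
        raise ValueError("history length k must be >= 1")
    if k >= n:
        raise ValueError("history too long")
    kx = k
    ko = k if condition_history else 1
    x_future = x[k:]
    x_past = _history_columns(x, k, n)[:kx]
    y_past = _history_columns(y, k, n)[:ko]
    z_past = [c for z, _ in zs for c in _history_columns(z, k, n)[:ko]]
    alphabets = {
        "x": sx,
        "y": sy,
        "z": [sz for _, sz in zs],
        "kx": kx,
        "ko": ko,
    }
    return x_future, x_past, y_past, z_past, alphabets


def conditional_transfer_entropy(
    target,
    source,
    conditioners=(),
    k: int = 1,
    condition_history: bool = True,
    source_role: str = "",
    target_role: str = "",
    conditioner_roles: tuple[str, ...] = (),
) -> CTEEstimate:
    """Plug-in conditional transfer entropy source -> target, in bits.

    With an empty conditioner list this is the ordinary (bivariate)
    transfer entropy.  ``condition_history=False`` restricts source and
    conditioners to a single lag while the target keeps ``k`` lags.
    """
    xf, xp, yp, zp, ab = build_te_states(
        target, source, conditioners, k=k, condition_history=condition_history
    )
    sx, sy = ab["x"], ab["y"]
    zbases = [sz for sz in ab["z"] for _ in range(ab["ko"])]
    # H(Xf, Xp, Zp) - H(Xp, Zp) - H(Xf, Xp, Yp, Zp) + H(Xp, Yp, Zp)
    cols_xz = xp + zp
    bases_xz = [sx] * len(xp) + zbases
    ybases = [sy] * len(yp)

    def H(cols, bases):
        code, _ = encode_columns(cols, bases)
        counts = np.bincount(_compact(code))
        return _entropy_bits_from_counts(counts[counts > 0], len(code))

    h1 = H([xf] + cols_xz, [sx] + bases_xz)
    h2 = H(cols_xz, bases_xz)
    h3 = H([xf] + cols_xz + yp, [sx] + bases_xz + ybases)
    h4 = H(cols_xz + yp, bases_xz + ybases)
    value = (h1 - h2) - (h3 - h4)
    return CTEEstimate(
        value=float(value),
        k=k,
        n_transitions=len(xf),
        source_role=source_role,
        target_role=target_role,
        conditioner_roles=tuple(conditioner_roles),
    )


def _compact(codes: np.ndarray) -> np.ndarray:
    """Relabel codes to a dense 0..m-1 range so bincount stays small."""
    _, inv = np.unique(codes, return_inverse=True)
    return inv
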