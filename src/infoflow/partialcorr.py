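"""Sign of a detected association via lagged partial rank correlation.

Transfer entropy is sign-blind, so each significant directed link is
followed up with the Spearman partial correlation between the past of
the source and the present of the target, controlling for the past of
the target and the past of the conditioner.  Rank transformation first,
then the residual method: regress source and target ranks on the
control ranks (with intercept) and correlate the residuals.  The 95%
confidence interval comes from the Fisher z transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    ci95: tuple[float, float]
    p_value: float
    lag: int
    n: int
    controls: tuple[str, ...] = ()


def _rank(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    if np.all(r == r[0]):
        raise ValueError("degenerate ranks: constant series")
    return r


def partial_rank_correlation(x, y, controls, n_for_ci: int | None = None) -> tuple[float, tuple[float, float], float]:
    """Partial Spearman correlation of x and y given control columns.

    Residual method on rank-transformed data; returns (rho, ci95, p).
    The p-value is a t test with ``n - 2 - n_controls`` degrees of
    freedom; the Fisher-z CI uses ``1/sqrt(n - 3)``.
    """
    xr, yr = _rank(np.asarray(x, float)), _rank(np.asarray(y, float))
    ctrl = np.column_stack([_rank(np.asarray(c, float)) for c in controls])
    n = len(xr)
    design = np.column_stack([np.ones(n), ctrl])
    bx, *_ = np.linalg.lstsq(design, xr, rcond=None)
    by, *_ = np.linalg.lstsq(design, yr, rcond=None)
    rx = xr - design @ bx
    ry = yr - design @ by
    rho = float(np.corrcoef(rx, ry)[0, 1])
    g = ctrl.shape[1]
    df = n - 2 - g
    rho_c = np.clip(rho, -0.999999999, 0.999999999)
    tstat = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2 * stats.t.sf(abs(tstat), df))
    n_ci = n if n_for_ci is None else n_for_ci
    z = np.arctanh(rho_c)
    half = stats.norm.ppf(0.975) / np.sqrt(n_ci - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return rho, ci, p


def lagged_partial_correlation(
    target,
    source,
    conditioner,
    lag: int = 1,
    controls_label: tuple[str, ...] = ("target_past", "conditioner_past"),
) -> PartialCorrResult:
    """Sign analysis for one directed link at the given lag (days).

    Correlates ``source[t - lag]`` with ``target[t]`` given
    ``target[t - lag]`` and ``conditioner[t - lag]``, all
    rank-transformed.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    tgt = np.asarray(target, float)
    src = np.asarray(source, float)
    cnd = np.asarray(conditioner, float)
    if not (len(tgt) == len(src) == len(cnd)):
        raise ValueError("unaligned series")
    if len(tgt) <= lag + 3:
        raise ValueError("series too short for the requested lag")
    y_now = tgt[lag:]
    x_past = src[:-lag]
    controls = [tgt[:-lag], cnd[:-lag]]
    rho, ci, p = partial_rank_correlation(x_past, y_now, controls)
    return PartialCorrResult(
        rho=rho, ci95=ci, p_value=p, lag=lag, n=len(y_now),
        controls=tuple(controls_label),
    )
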