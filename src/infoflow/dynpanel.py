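"""Deterministic coupled-map panels for the CCM stage.

Cross mapping presumes the series are observations of coupled
*deterministic* dynamics; the Poisson/Markov panels of
:func:`infoflow.synth.gen_panel` deliberately are not (they model count
noise for the information-theoretic stage).  This generator provides
the study-shaped counterpart CCM can legitimately act on: one national
driver logistic map, observed as a print-dated media series, that
forces each area's negative-tweet map, with independent maps for the
other roles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import DailySeries


def gen_dynamical_panel(
    n_areas: int = 2,
    n_days: int = 3745,
    coupling: float = 0.3,
    seed: int = 0,
    r_driver: float = 3.7,
    r_driven: float = 3.8,
    scale: float = 100.0,
    base: float = 10.0,
    burn_in: int = 300,
    start: str = "2010-10-01",
) -> tuple[list[DailySeries], dict]:
    """Study-shaped panel whose MPB->NT links are coupled logistic maps.

    The national driver map ``d`` evolves freely; each area's NT map
    obeys ``x_{t+1} = x_t (r - r x_t - coupling * d_t)``.  MLC and PT
    are independent maps.  Counts are ``base + scale * map`` and the
    MPB series is print-dated (value on day t+1 observes the driver
    state of day t) so the pipeline's backward shift restores
    alignment.  Returns ``(series_list, truth)``.
    """
    if not 0.0 <= coupling < 0.5:
        raise ValueError("coupling must lie in [0, 0.5) to keep maps bounded")
    rng = np.random.default_rng(seed)
    total = n_days + burn_in + 1

    def free_map(r):
        v = np.empty(total)
        v[0] = rng.uniform(0.2, 0.8)
        for t in range(total - 1):
            v[t + 1] = v[t] * (r - r * v[t])
        return v

    driver = free_map(r_driver)
    dates = pd.date_range(start, periods=n_days, freq="D")

    def to_counts(traj):
        return base + scale * traj

    # MPB printed on day t observes driver[t-1]
    mpb_vals = to_counts(driver[burn_in : burn_in + n_days + 1])
    series = [
        DailySeries(dates=dates, values=mpb_vals[:n_days], role="MPB", area="")
    ]
    truth = {"driver": driver[burn_in + 1 : burn_in + 1 + n_days],
             "coupling": coupling,
             "true_links": {("MPB", "NT")} if coupling > 0 else set()}
    for a in range(n_areas):
        area = f"area{a:02d}"
        x = np.empty(total)
        x[0] = rng.uniform(0.2, 0.8)
        for t in range(total - 1):
            x[t + 1] = x[t] * (r_driven - r_driven * x[t] - coupling * driver[t])
            if not 0.0 < x[t + 1] < 1.0:
                raise ValueError("divergent parameters: driven map left (0, 1)")
        # distinct chaotic parameters (periodic-window values such as
        # r = 3.5 or 3.83 would make independent series cross-mappable)
        nt = to_counts(x[burn_in + 1 : burn_in + 1 + n_days])
        mlc = to_counts(free_map(3.9)[burn_in + 1 : burn_in + 1 + n_days])
        pt = to_counts(free_map(3.99)[burn_in + 1 : burn_in + 1 + n_days])
        series.append(DailySeries(dates=dates, values=mlc, role="MLC", area=area))
        series.append(DailySeries(dates=dates, values=pt, role="PT", area=area))
        series.append(DailySeries(dates=dates, values=nt, role="NT", area=area))
    return series, truth
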