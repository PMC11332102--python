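import numpy as np
import pandas as pd
import pytest

from infoflow import DailySeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def iid_uniform3():
    """Three mutually independent uniform 3-symbol series, study length."""
    r = np.random.default_rng(42)
    return tuple(r.integers(0, 3, size=3745) for _ in range(3))


def make_daily(values, role="NT", area="test", start="2012-01-01"):
    values = np.asarray(values, dtype=float)
    return DailySeries(
        dates=pd.date_range(start, periods=len(values), freq="D"),
        values=values,
        role=role,
        area=area,
    )


@pytest.fixture
def make_daily_series():
    return make_daily
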