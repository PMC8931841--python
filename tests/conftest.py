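import numpy as np
import pytest

import trendshift as ts


@pytest.fixture
def epochs():
    return ts.EpochConfig()


@pytest.fixture
def null_series():
    """Default-condition synthetic series with no intervention effect."""
    series, truth = ts.generate_series(ts.SyntheticSpec(seed=11))
    return series, truth


@pytest.fixture
def winter_reduced_series():
    """Synthetic series whose post-intervention winter is halved."""
    series, truth = ts.generate_series(
        ts.SyntheticSpec(seed=12, season_effects={"winter": 0.5}))
    return series, truth


def make_series(values, term="t", start="2020-03-01", missing=None):
    """Small helper building a weekly SearchSeries from plain values."""
    values = np.asarray(values, float)
    n = len(values)
    weeks = np.arange(np.datetime64(start, "D"),
                      np.datetime64(start, "D") + np.timedelta64(7 * n, "D"),
                      np.timedelta64(7, "D"))
    if missing is None:
        missing = np.zeros(n, bool)
    vals = np.where(missing, np.nan, values)
    return ts.SearchSeries(term, "US", weeks, vals, np.asarray(missing, bool))
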