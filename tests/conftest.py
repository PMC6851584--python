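import numpy as np
import pandas as pd
import pytest

from winterclim import GenParams, StationMeta, StationSeries, generate_daily_series


@pytest.fixture(scope="session")
def meta():
    return StationMeta("TEST001", 45.0, -72.0, "test station")


@pytest.fixture(scope="session")
def short_series(meta):
    """Three synthetic winters, fixed seed."""
    return generate_daily_series(GenParams(n_years=3, seed=42), meta=meta)


@pytest.fixture(scope="session")
def long_series(meta):
    """Thirty synthetic winters for trend-level tests, fixed seed."""
    return generate_daily_series(GenParams(n_years=30, seed=7), meta=meta)


def make_series(
    dates, tmin=None, tmax=None, prcp=None, snowfall=None, snow_depth=None,
    station_id="MANUAL", longitude=-72.0,
):
    """Hand-built StationSeries with NaN defaults for absent variables."""
    idx = pd.DatetimeIndex(pd.to_datetime(dates), name="date")
    n = len(idx)

    def col(v):
        if v is None:
            return np.full(n, np.nan)
        return np.asarray(v, dtype=float)

    df = pd.DataFrame(
        {
            "tmin": col(tmin),
            "tmax": col(tmax),
            "prcp": col(prcp),
            "snowfall": col(snowfall),
            "snow_depth": col(snow_depth),
        },
        index=idx,
    )
    return StationSeries(StationMeta(station_id, 45.0, longitude), df)
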