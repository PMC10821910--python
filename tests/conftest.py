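import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ricegap import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_weather():
    """Build a constant-valued daily weather frame for closed-form checks."""

    def _make(days=400, tmax=29.0, tmin=19.0, srad=18.0, precip=0.0,
              start="2000-01-01"):
        dates = pd.date_range(start, periods=days, freq="D")
        def col(v):
            return np.full(days, float(v)) if np.isscalar(v) else np.asarray(v, float)
        return pd.DataFrame({"date": dates, "srad": col(srad), "tmax": col(tmax),
                             "tmin": col(tmin), "precip": col(precip)})

    return _make


@pytest.fixture(scope="session")
def monsoon_weather():
    """20 years of default-parameter monsoonal weather (seed 0)."""
    return synthetic.gen_weather(synthetic.WeatherGeneratorParams(seed=0), 20)


@pytest.fixture(scope="session")
def small_study():
    """A 3-country synthetic study reused by aggregation tests."""
    return synthetic.gen_site_network(3, seed=11, years=6)
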