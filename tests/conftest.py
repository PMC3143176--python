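"""Shared fixtures: small synthetic surveys, grids, and weather series."""

import numpy as np
import pandas as pd
import pytest

from aedespop.habitat import build_replicated_grid
from aedespop.synthetic_data import SurveyGenParams, generate_survey_subset
from aedespop.weather import WeatherSeries


def constant_weather(n_days: int, tmin: float, tmax: float, rain: float = 2.0,
                     rh: float = 80.0) -> WeatherSeries:
    """A flat weather series for deterministic biology tests."""
    return WeatherSeries(
        pd.DataFrame(
            {
                "date": pd.date_range("2000-01-01", periods=n_days, freq="D"),
                "tmin": tmin,
                "tmax": tmax,
                "rain": rain,
                "rh": rh,
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_survey():
    """4x3 block with ~40 containers — smallest interesting habitat."""
    p = SurveyGenParams(n_rows=4, n_cols=3, target_container_total=40)
    return generate_survey_subset(p, seed=7)


@pytest.fixture(scope="session")
def tiny_grid(tiny_survey):
    return build_replicated_grid(tiny_survey, 4, 3, 1, seed=8)


@pytest.fixture(scope="session")
def warm_weather():
    """120 days of constant warm, wet weather (hatch-permissive)."""
    return constant_weather(120, 24.0, 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
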