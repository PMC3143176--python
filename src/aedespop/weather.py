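"""Daily weather series: reading, validation, and synthesis.

All biological rates in the simulator are driven by a daily weather record
(min/max air temperature, rainfall, relative humidity).  Real station data
can be read from a simple CSV dialect; for study conditions without archived
data, two synthetic regimes are provided:

* an *equatorial* regime (Iquitos-like): essentially aseasonal, warm
  (mean daily maximum ~32.2 degC, minimum ~21.4 degC), with frequent rain
  totalling ~2,878 mm per year;
* a *temperate* regime (Buenos Aires-like): strong seasonality with a
  Southern-hemisphere phase, i.e. coldest around mid-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "WeatherRegimeParams",
    "WeatherValidationError",
    "WeatherGapError",
    "read_weather",
    "write_weather",
    "generate_weather",
    "equatorial_regime",
    "temperate_regime",
]

_COLUMNS = ["date", "tmin", "tmax", "rain", "rh"]


class WeatherValidationError(ValueError):
    """A weather row violates a physical invariant (tmin > tmax, rain < 0, ...)."""


class WeatherGapError(ValueError):
    """Dates in a weather series are not strictly consecutive."""


@dataclass(frozen=True)
class DailyWeather:
    """One validated day of weather."""

    date: object
    t_min: float
    t_max: float
    rainfall: float
    rel_humidity: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise WeatherValidationError("t_min > t_max")
        if self.rainfall < 0:
            raise WeatherValidationError("negative rainfall")
        if not 0 <= self.rel_humidity <= 100:
            raise WeatherValidationError("relative humidity outside [0, 100]")

    @property
    def t_mean(self) -> float:
        return 0.5 * (self.t_min + self.t_max)


@dataclass(frozen=True)
class WeatherSeries:
    """A contiguous daily weather record.

    Wraps a DataFrame with columns ``date, tmin, tmax, rain, rh`` (one row per
    calendar day, strictly consecutive dates).  Construction validates all
    invariants; downstream code can rely on them.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise WeatherValidationError(f"missing columns: {missing}")
        if len(df) == 0:
            raise WeatherValidationError("empty weather series")
        dates = pd.to_datetime(df["date"])
        gaps = dates.diff().dt.days.iloc[1:]
        if (gaps != 1).any():
            first_bad = dates.iloc[int(np.argmax(gaps.to_numpy() != 1)) + 1]
            raise WeatherGapError(
                f"dates not strictly consecutive near {first_bad.date()}"
            )
        if (df["tmin"] > df["tmax"]).any():
            bad = df.loc[df["tmin"] > df["tmax"], "date"].iloc[0]
            raise WeatherValidationError(f"tmin > tmax on {bad}")
        if (df["rain"] < 0).any():
            bad = df.loc[df["rain"] < 0, "date"].iloc[0]
            raise WeatherValidationError(f"negative rainfall on {bad}")
        if ((df["rh"] < 0) | (df["rh"] > 100)).any():
            bad = df.loc[(df["rh"] < 0) | (df["rh"] > 100), "date"].iloc[0]
            raise WeatherValidationError(f"relative humidity outside [0, 100] on {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    def day(self, i: int) -> DailyWeather:
        r = self.frame.iloc[i]
        return DailyWeather(
            date=r["date"], t_min=float(r["tmin"]), t_max=float(r["tmax"]),
            rainfall=float(r["rain"]), rel_humidity=float(r["rh"]),
        )

    @property
    def tmin(self) -> np.ndarray:
        return self.frame["tmin"].to_numpy(float)

    @property
    def tmax(self) -> np.ndarray:
        return self.frame["tmax"].to_numpy(float)

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def rain(self) -> np.ndarray:
        return self.frame["rain"].to_numpy(float)

    @property
    def rh(self) -> np.ndarray:
        return self.frame["rh"].to_numpy(float)


@dataclass(frozen=True)
class WeatherRegimeParams:
    """Parameters of the sinusoid-plus-noise synthetic weather generator.

    Temperatures follow ``mean + amplitude * cos(2*pi*doy/365.25)`` plus
    Gaussian daily noise; with the Southern-hemisphere phase convention the
    seasonal term peaks at the start of the calendar year (austral summer)
    and bottoms out at mid-year.  Rain is a Bernoulli wet-day indicator times
    an exponential depth, with the depth scale solved so the expected annual
    total equals ``annual_rainfall``.
    """

    mean_t_max: float
    mean_t_min: float
    amp_t_max: float
    amp_t_min: float
    annual_rainfall: float
    rain_prob: float
    noise_scale: float
    mean_rh: float = 75.0
    amp_rh: float = 0.0

    def __post_init__(self) -> None:
        if self.annual_rainfall < 0:
            raise ValueError("annual_rainfall must be >= 0")
        if self.amp_t_max < 0 or self.amp_t_min < 0:
            raise ValueError("seasonal amplitudes must be >= 0")
        if not 0 < self.rain_prob <= 1:
            raise ValueError("rain_prob must be in (0, 1]")


def equatorial_regime() -> WeatherRegimeParams:
    """Iquitos-like aseasonal warm regime.

    Long-run mean daily maximum 32.2 degC (5-95% range roughly 29-35 degC),
    mean minimum 21.4 degC, ~2,878 mm annual rainfall falling frequently all
    year, high humidity.
    """
    return WeatherRegimeParams(
        mean_t_max=32.2,
        mean_t_min=21.4,
        amp_t_max=0.0,
        amp_t_min=0.0,
        annual_rainfall=2878.0,
        rain_prob=0.6,
        noise_scale=1.8,
        mean_rh=85.0,
        amp_rh=0.0,
    )


def temperate_regime() -> WeatherRegimeParams:
    """Buenos Aires-like seasonal regime, Southern-hemisphere phase.

    Warm summers (daily maxima around 30 degC in January), cool winters
    (maxima around 15 degC in July), ~1,200 mm annual rainfall, humidity
    oscillating between roughly 55% and 75%.
    """
    return WeatherRegimeParams(
        mean_t_max=22.5,
        mean_t_min=12.5,
        amp_t_max=7.5,
        amp_t_min=6.5,
        annual_rainfall=1200.0,
        rain_prob=0.3,
        noise_scale=2.0,
        mean_rh=65.0,
        amp_rh=10.0,
    )


def generate_weather(
    regime: WeatherRegimeParams,
    n_days: int,
    seed: int,
    start: str = "2000-01-01",
) -> WeatherSeries:
    """Draw a synthetic daily weather series of length ``n_days``.

    Same (regime, n_days, seed, start) always produces the identical series.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    doy = np.arange(n_days, dtype=float)
    phase = np.cos(2.0 * np.pi * doy / 365.25)

    t_max = regime.mean_t_max + regime.amp_t_max * phase
    t_min = regime.mean_t_min + regime.amp_t_min * phase
    # shared day-to-day anomaly plus independent jitter keeps tmin <= tmax
    anomaly = rng.normal(0.0, regime.noise_scale, n_days)
    t_max = t_max + anomaly + rng.normal(0.0, 0.3, n_days)
    t_min = t_min + anomaly + rng.normal(0.0, 0.3, n_days)
    t_min = np.minimum(t_min, t_max - 0.1)

    wet = rng.random(n_days) < regime.rain_prob
    mean_depth = regime.annual_rainfall / (365.25 * regime.rain_prob)
    rain = np.where(wet, rng.exponential(mean_depth, n_days), 0.0)

    rh = regime.mean_rh - regime.amp_rh * phase + rng.normal(0.0, 3.0, n_days)
    rh = np.clip(rh, 5.0, 100.0)

    frame = pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n_days, freq="D"),
            "tmin": t_min,
            "tmax": t_max,
            "rain": rain,
            "rh": rh,
        }
    )
    return WeatherSeries(frame)


def read_weather(path) -> WeatherSeries:
    """Read a weather CSV (``date,tmin,tmax,rain,rh``; ISO dates, one row/day)."""
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return WeatherSeries(df)


def write_weather(series: WeatherSeries, path) -> None:
    df = series.frame.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
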