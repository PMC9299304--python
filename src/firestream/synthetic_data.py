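"""Synthetic daily weather / water-temperature generator with an injectable fire effect.

The generator produces multi-year daily series carrying the statistical
structure the inference stages assume — a seasonal air-temperature cycle with
AR(1) noise, intermittent precipitation with season-specific occurrence and
intensity, a smooth PET cycle in antiphase with precipitation, and water
temperature driven by *smoothed* air temperature plus recent precipitation with
autocorrelated noise. A season-specific step change (optionally decaying year
over year) can then be injected into post-fire water temperatures, giving every
stage a known truth to recover. It is test scaffolding: it makes no claim of
energy-balance realism (no snowpack, shade, or flow feedback).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from firestream.timeseries_io import DailySeries, SeasonWindow, build_season_windows

__all__ = [
    "SyntheticConfig",
    "simulate_weather",
    "simulate_water_temperature",
    "inject_fire_effect",
    "simulate_site",
]

WINTER_MONTHS = (12, 1, 2)
SUMMER_MONTHS = (7, 8, 9)


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic site.

    Defaults emulate a rain-dominated Pacific-Northwest montane watershed:
    annual mean air temperature ~8.6 °C with ~10.6 °C seasonal amplitude, wet
    winters (~8 mm/day) and dry summers (~1 mm/day), and water temperature
    tracking the 30-day mean air temperature with slope ~0.35 °C/°C — in the
    range of observed weekly air–water slopes for such streams — cooled
    slightly by recent precipitation (runoff advection).
    """

    n_pre_years: int = 7
    n_post_years: int = 3
    fire_date: date = date(2008, 7, 15)

    # air temperature: annual sinusoid (peak mid-July) + AR(1) noise
    tair_mean_annual: float = 8.6  # °C
    tair_amplitude: float = 10.6  # °C, half peak-to-trough
    tair_ar1: float = 0.6
    tair_noise_sd: float = 1.5  # °C, innovation sd

    # precipitation: Bernoulli occurrence x exponential intensity, by season
    precip_winter_mean: float = 8.0  # mm/day averaged over DJF
    precip_summer_mean: float = 1.0  # mm/day averaged over JAS
    precip_wet_prob_winter: float = 0.55
    precip_wet_prob_summer: float = 0.15

    # PET: non-negative annual sinusoid peaking mid-summer
    pet_mean: float = 2.5  # mm/day
    pet_amplitude: float = 2.5  # mm/day

    # water response
    water_intercept: float = 3.0  # °C
    water_slope: float = 0.35  # °C water per °C of smoothed air temperature
    water_smoothing_window: int = 30  # days
    precip_cooling: float = 0.01  # °C per mm of 7-day precipitation sum
    water_noise_ar1: float = 0.5
    water_noise_sd: float = 0.3  # °C, innovation sd

    # fire effect: step shift on post-fire season days, decaying per year
    delta_summer: float = 0.0  # °C
    delta_winter: float = 0.0  # °C
    decay_per_year: float = 0.0  # fraction per post-fire year

    seed: int = 0

    def validate(self) -> None:
        if self.tair_noise_sd < 0 or self.water_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (abs(self.tair_ar1) < 1 and abs(self.water_noise_ar1) < 1):
            raise ValueError("AR(1) coefficients must satisfy |phi| < 1")
        if self.water_smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")
        if not 0.0 <= self.decay_per_year <= 1.0:
            raise ValueError("decay_per_year must be in [0, 1]")
        for p in (self.precip_wet_prob_winter, self.precip_wet_prob_summer):
            if not 0.0 < p <= 1.0:
                raise ValueError("wet-day probabilities must be in (0, 1]")
        if self.precip_winter_mean < 0 or self.precip_summer_mean < 0:
            raise ValueError("precipitation means must be >= 0")
        if self.n_pre_years < 3 or self.n_post_years < 1:
            raise ValueError("need >= 3 pre-fire and >= 1 post-fire years")


def _date_index(config: SyntheticConfig) -> pd.DatetimeIndex:
    start = date(config.fire_date.year - config.n_pre_years, 1, 1)
    end_year = config.fire_date.year + config.n_post_years
    if config.fire_date.month >= 10:  # late-season fire: post winters run a year later
        end_year += 1
    return pd.date_range(start, date(end_year, 12, 31), freq="D", name="date")


def _annual_cycle(index: pd.DatetimeIndex, mean: float, amplitude: float) -> np.ndarray:
    # peak near mid-July (day of year 196), trough mid-January
    doy = index.dayofyear.to_numpy()
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - 196) / 365.25)


def _ar1(n: int, phi: float, innov_sd: float, rng: np.random.Generator) -> np.ndarray:
    if innov_sd == 0.0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, innov_sd, size=n)
    if phi == 0.0:
        return innov
    out = lfilter([1.0], [1.0, -phi], innov)
    # stationary start instead of a zero start
    out += rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi * phi)) * phi ** np.arange(1, n + 1)
    return out


def simulate_weather(config: SyntheticConfig) -> DailySeries:
    """Generate daily air temperature, precipitation, and PET (twater left missing).

    Occurrence/intensity parameters are piecewise by month so that the
    configured winter (DJF) and summer (JAS) daily means are exact
    expectations; shoulder months use the average of the two regimes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    index = _date_index(config)
    n = len(index)

    tair = _annual_cycle(index, config.tair_mean_annual, config.tair_amplitude)
    tair = tair + _ar1(n, config.tair_ar1, config.tair_noise_sd, rng)

    month = index.month.to_numpy()
    wet_prob = np.full(
        n, (config.precip_wet_prob_winter + config.precip_wet_prob_summer) / 2.0
    )
    mean_daily = np.full(n, (config.precip_winter_mean + config.precip_summer_mean) / 2.0)
    winter = np.isin(month, WINTER_MONTHS)
    summer = np.isin(month, SUMMER_MONTHS)
    wet_prob[winter] = config.precip_wet_prob_winter
    wet_prob[summer] = config.precip_wet_prob_summer
    mean_daily[winter] = config.precip_winter_mean
    mean_daily[summer] = config.precip_summer_mean
    wet = rng.random(n) < wet_prob
    intensity = rng.exponential(1.0, size=n) * (mean_daily / wet_prob)
    precip = np.where(wet, intensity, 0.0)

    pet = np.clip(_annual_cycle(index, config.pet_mean, config.pet_amplitude), 0.0, None)

    df = pd.DataFrame(
        {
            "twater": np.nan,
            "tair": tair,
            "precip": precip,
            "pet": pet,
            "flow": np.nan,
        },
        index=index,
    )
    return DailySeries("synthetic", df, {"generator_seed": config.seed})


def simulate_water_temperature(weather: DailySeries, config: SyntheticConfig) -> DailySeries:
    """Add daily water temperature driven by smoothed air temperature.

    twater = intercept + slope * trailing-mean(tair, window)
             - precip_cooling * trailing-sum(precip, 7) + AR(1) noise,
    floored at 0 °C. Trailing windows use min_periods=1 so the record start
    has a shortened warm-up rather than missing values.
    """
    config.validate()
    df = weather.data
    for col in ("tair", "precip", "pet"):
        if df[col].isna().any():
            raise ValueError(f"weather column {col!r} has missing values")
    rng = np.random.default_rng([config.seed, 1])
    smoothed = df["tair"].rolling(config.water_smoothing_window, min_periods=1).mean()
    wetness = df["precip"].rolling(7, min_periods=1).sum()
    det = (
        config.water_intercept
        + config.water_slope * smoothed
        - config.precip_cooling * wetness
    )
    noise = _ar1(len(df), config.water_noise_ar1, config.water_noise_sd, rng)
    twater = np.clip(det.to_numpy() + noise, 0.0, None)
    out = weather.copy()
    out.data["twater"] = twater
    return out


def inject_fire_effect(
    series: DailySeries, windows: list[SeasonWindow], config: SyntheticConfig
) -> DailySeries:
    """Shift post-fire season water temperatures by the configured deltas.

    Post-fire year k (k = 1, 2, ...) of each season receives an additive
    shift delta_season * (1 - decay_per_year)**(k-1) on every day of the
    window. Other days are untouched (bit-equal when deltas are zero).
    """
    config.validate()
    for win in windows:
        inside = win.contains(config.fire_date)
        if win.fire_phase == "fire_year_excluded" and not inside:
            raise ValueError(
                f"windows inconsistent with fire_date {config.fire_date}: "
                f"excluded window {win.season} {win.season_year} does not contain it"
            )
        if win.fire_phase != "fire_year_excluded" and inside:
            raise ValueError(
                f"windows inconsistent with fire_date {config.fire_date}: "
                f"{win.fire_phase} window {win.season} {win.season_year} contains it"
            )
    out = series.copy()
    deltas = {"summer": config.delta_summer, "winter": config.delta_winter}
    for season in ("winter", "summer"):
        post = sorted(
            (w for w in windows if w.season == season and w.fire_phase == "post"),
            key=lambda w: w.start,
        )
        for k, win in enumerate(post, start=1):
            shift = deltas[season] * (1.0 - config.decay_per_year) ** (k - 1)
            if shift == 0.0:
                continue
            sl = slice(str(win.start), str(win.end))
            out.data.loc[sl, "twater"] = out.data.loc[sl, "twater"] + shift
    return out


def simulate_site(
    config: SyntheticConfig, n_pre_max: int | None = None
) -> tuple[DailySeries, list[SeasonWindow]]:
    """Full generator pipeline: weather -> water temperature -> fire effect.

    Returns the series together with its season windows (built with
    ``n_pre_max`` defaulting to the configured number of pre-fire years).
    """
    weather = simulate_weather(config)
    series = simulate_water_temperature(weather, config)
    windows = build_season_windows(
        series,
        config.fire_date,
        n_pre_max=n_pre_max or config.n_pre_years,
        n_post=config.n_post_years,
    )
    if config.delta_summer != 0.0 or config.delta_winter != 0.0:
        series = inject_fire_effect(series, windows, config)
    return series, windows
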