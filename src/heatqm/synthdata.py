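"""Synthetic daily temperature and emergency-department count generators.

The real inputs to this analysis -- station observations of daily minimum
temperature, a multi-member regional-climate-model ensemble, and protected
hospital ED records -- are emulated here with seeded generators that carry
the statistical structure the downstream methods assume:

* observations: an annual harmonic mean cycle plus AR(1) Gaussian noise;
* model series: an independent realization of the same weather process,
  distorted by an additive bias, a multiplicative bias on anomalies, an
  extra additive bias above an upper quantile (the quantile-dependent bias
  quantile mapping exists to remove), and a linear warming trend in the
  projection period;
* ED counts: overdispersed counts from a log-linear model with a known
  temperature exposure-response curve, seasonal trend, day-of-week and
  holiday effects.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .series import daily_series, warm_season

#: day of year of the warm peak of the seasonal harmonic (mid-July)
_SEASONAL_PEAK_DOY = 199.0
_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ObsTempConfig:
    """Observed daily minimum temperature process.

    The marginal mean on day t is ``mean_level + seasonal_amplitude *
    cos(2*pi*(doy - peak)/365.25)``; residuals are AR(1) with innovation
    standard deviation ``noise_sd`` (stationary sd ``noise_sd /
    sqrt(1 - ar1^2)``).  Defaults are sized to a humid-subtropical city:
    winter minima near 6 deg C, summer minima near 24 deg C, day-to-day
    residual sd around 3.5 deg C.
    """

    start_date: str = "1993-01-01"
    end_date: str = "2004-12-31"
    mean_level: float = 15.0
    seasonal_amplitude: float = 9.0
    ar1_coefficient: float = 0.7
    noise_sd: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError("end_date must be after start_date")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")


@dataclass(frozen=True)
class ModelBiasConfig:
    """Distortion of one climate model relative to the observed process.

    ``additive_bias`` shifts every value; ``scale_bias`` multiplies
    deviations from ``mean_level`` (so it scales both the seasonal cycle and
    the noise, and equals the raw normalized standard deviation);
    ``tail_bias`` is added to values above the ``tail_quantile`` of the
    model's own hindcast distribution; ``warming_trend`` (deg C per decade)
    is a linear trend applied over the projection period.
    """

    additive_bias: float = 0.0
    scale_bias: float = 1.0
    tail_bias: float = 0.0
    tail_quantile: float = 0.9
    warming_trend: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if not self.scale_bias > 0:
            raise ValueError("scale_bias must be positive")
        if not 0 < self.tail_quantile < 1:
            raise ValueError("tail_quantile must be in (0, 1)")


@dataclass(frozen=True)
class HealthGenConfig:
    """Data-generating log-linear model for daily ED counts.

    log mean = baseline_log_rate + true_erf(3-day mean temperature)
             + season_trend_amplitude * cos(annual phase)
             + dow_effects[weekday] + holiday_effect * 1{holiday}.
    Counts are negative-binomial with variance = dispersion * mean
    (Poisson when dispersion == 1).
    """

    baseline_log_rate: float = 7.6
    true_erf: Callable[[np.ndarray], np.ndarray] = lambda x: 0.01 * (x - 7.0)
    dow_effects: Sequence[float] = (0.04, 0.01, 0.0, 0.0, 0.01, -0.06, -0.08)
    holiday_effect: float = -0.05
    holidays: Sequence[str] = ()
    season_trend_amplitude: float = 0.05
    dispersion: float = 1.3
    lag_window: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.dispersion >= 1:
            raise ValueError("dispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")


def _seasonal_mean(index: pd.DatetimeIndex, config: ObsTempConfig) -> np.ndarray:
    doy = index.dayofyear.to_numpy(dtype=float)
    return config.mean_level + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - _SEASONAL_PEAK_DOY) / _DAYS_PER_YEAR
    )


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(n)
    e = np.empty(n)
    # start from the stationary distribution so the series has no burn-in
    e[0] = z[0] * sd / np.sqrt(1 - phi * phi)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + sd * z[t]
    return e


def _weather_realization(index: pd.DatetimeIndex, config: ObsTempConfig,
                         seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _seasonal_mean(index, config) + _ar1_noise(
        len(index), config.ar1_coefficient, config.noise_sd, rng
    )


def gen_observed_temperature(config: ObsTempConfig) -> pd.Series:
    """One observed-temperature value per calendar day of the config period."""
    index = pd.date_range(config.start_date, config.end_date, freq="D")
    return daily_series(index, _weather_realization(index, config, config.seed),
                        name="tmin_obs")


def gen_model_series(
    obs_config: ObsTempConfig,
    bias: ModelBiasConfig,
    hist_period: tuple[str, str],
    proj_period: tuple[str, str],
) -> tuple[pd.Series, pd.Series]:
    """Hindcast and projection series for one biased climate model.

    The hindcast is an independent realization of the observed weather
    process (seeded by ``bias.seed``) passed through the bias transform; the
    projection additionally carries the linear warming trend, measured from
    the start of the projection period.
    """
    h0, h1 = pd.Timestamp(hist_period[0]), pd.Timestamp(hist_period[1])
    p0, p1 = pd.Timestamp(proj_period[0]), pd.Timestamp(proj_period[1])
    if h1 <= h0 or p1 <= p0:
        raise ValueError("each period must have positive length")
    if p0 <= h1:
        raise ValueError("projection period must start after the historical period ends")

    hist_idx = pd.date_range(h0, h1, freq="D")
    proj_idx = pd.date_range(p0, p1, freq="D")

    raw_h = _weather_realization(hist_idx, obs_config, bias.seed)
    raw_p = _weather_realization(proj_idx, obs_config, bias.seed + 1)

    def distort(values: np.ndarray, threshold: float) -> np.ndarray:
        out = (obs_config.mean_level + bias.additive_bias
               + bias.scale_bias * (values - obs_config.mean_level))
        out = out + np.where(out > threshold, bias.tail_bias, 0.0)
        return out

    # tail threshold from the model's own hindcast distribution so the
    # quantile-dependent bias is consistent across periods
    base_h = (obs_config.mean_level + bias.additive_bias
              + bias.scale_bias * (raw_h - obs_config.mean_level))
    threshold = float(np.quantile(base_h, bias.tail_quantile))

    hind = distort(raw_h, threshold)
    proj = distort(raw_p, threshold)
    years_elapsed = (proj_idx - p0).days.to_numpy(dtype=float) / _DAYS_PER_YEAR
    proj = proj + bias.warming_trend * years_elapsed / 10.0

    return (daily_series(hist_idx, hind, name="tmin_hindcast"),
            daily_series(proj_idx, proj, name="tmin_projection"))


def gen_ensemble(
    obs_config: ObsTempConfig,
    bias_configs: Sequence[ModelBiasConfig],
    hist_period: tuple[str, str],
    proj_period: tuple[str, str],
) -> list[tuple[pd.Series, pd.Series]]:
    """One (hindcast, projection) pair per ensemble member, distinct seeds."""
    if len(bias_configs) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    seeds = [b.seed for b in bias_configs]
    if len(set(seeds)) != len(seeds):
        raise ValueError("ensemble members must have distinct seeds")
    return [gen_model_series(obs_config, b, hist_period, proj_period)
            for b in bias_configs]


def moving_average(series: pd.Series, window: int) -> pd.Series:
    """Trailing moving average: value at t = mean of t, t-1, ..., t-window+1.

    The first ``window - 1`` days are NaN.  Shared with the health model,
    which uses the 3-day window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    return series.rolling(window, min_periods=window).mean()


def ed_log_mean(temperature: pd.Series, config: HealthGenConfig) -> pd.Series:
    """Linear predictor (log mean count) of the ED generating model.

    Defined on days where the trailing moving average of temperature exists;
    the first ``lag_window - 1`` days are dropped.
    """
    x = moving_average(temperature, config.lag_window).dropna()
    erf_vals = np.asarray(config.true_erf(x.to_numpy()), dtype=float)
    if not np.all(np.isfinite(erf_vals)):
        raise ValueError("true_erf is not evaluable over the generated temperature range")
    idx = x.index
    doy = idx.dayofyear.to_numpy(dtype=float)
    season = config.season_trend_amplitude * np.cos(
        2 * np.pi * (doy - _SEASONAL_PEAK_DOY) / _DAYS_PER_YEAR
    )
    dow = np.asarray(config.dow_effects, dtype=float)[idx.dayofweek]
    holidays = pd.DatetimeIndex(pd.to_datetime(list(config.holidays)))
    hol = np.where(idx.isin(holidays), config.holiday_effect, 0.0)
    return pd.Series(config.baseline_log_rate + erf_vals + season + dow + hol,
                     index=idx, name="log_mu")


def gen_ed_counts(temperature: pd.Series, config: HealthGenConfig) -> pd.Series:
    """Overdispersed daily ED counts driven by a known exposure-response.

    Negative-binomial with mean exp(linear predictor) and variance
    ``dispersion * mean``; exactly Poisson when dispersion == 1.
    """
    log_mu = ed_log_mean(temperature, config)
    mu = np.exp(log_mu.to_numpy())
    rng = np.random.default_rng(config.seed)
    if config.dispersion == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB2 parametrization: size r = mu/(phi-1), p = 1/phi gives
        # mean mu and variance phi*mu
        r = mu / (config.dispersion - 1.0)
        p = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, p)
    return pd.Series(counts.astype(float), index=log_mu.index, name="ed_count")


def calibrate_baseline(temperature: pd.Series, config: HealthGenConfig,
                       target_warm_mean: float = 2286.0) -> HealthGenConfig:
    """Return a config whose baseline makes the expected warm-season mean
    count equal ``target_warm_mean`` exactly (sampling noise aside)."""
    log_mu = ed_log_mean(temperature, config)
    warm = warm_season(log_mu)
    shift = np.log(target_warm_mean) - np.log(np.mean(np.exp(warm.to_numpy())))
    from dataclasses import replace
    return replace(config, baseline_log_rate=config.baseline_log_rate + float(shift))


def derive_seed(global_seed: int, *path: int | str) -> int:
    """Deterministic sub-seed derivation (< 2**31) from a global seed.

    Mixing the stage/member path through SeedSequence entropy keeps each
    member's stream stable when other members are added or removed.
    """
    tokens = [int.from_bytes(str(p).encode(), "little") % (2**31) if isinstance(p, str)
              else int(p) for p in path]
    ss = np.random.SeedSequence([int(global_seed)] + tokens)
    return int(ss.generate_state(1)[0] % (2**31))


def write_provenance(path, *, stage: str, seeds: dict, config: dict) -> None:
    """Emit a JSON sidecar recording every seed used by a generation stage."""
    record = {"stage": stage, "seeds": seeds, "config": config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
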