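"""Bias-correction fit statistics and ensemble between-model variability.

MBE  = mean(obs - model)            mean bias error, deg C
MAE  = mean |obs - model|           mean absolute error, deg C
RMSE = sqrt(mean (obs - model)^2)   root-mean-square error, deg C
NSD  = sd(model) / sd(obs)          normalized standard deviation, unitless

Sample (n-1) standard deviations throughout.  The ensemble spread summary
computes a within-model statistic first (default: the May-September period
mean of daily values), then the sample SD of that statistic across models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .series import align, WARM_MONTHS


@dataclass(frozen=True)
class FitMetrics:
    mbe: float
    mae: float
    rmse: float
    nsd: float


def compute_metrics(obs: pd.Series, model: pd.Series) -> FitMetrics:
    """Fit statistics between aligned observed and (corrected) model series."""
    align(obs, model)
    o = obs.to_numpy(dtype=float)
    m = model.to_numpy(dtype=float)
    ok = np.isfinite(o) & np.isfinite(m)
    o, m = o[ok], m[ok]
    if len(o) < 2:
        raise ValueError("need at least 2 paired non-missing days")
    sd_o = np.std(o, ddof=1)
    if sd_o == 0:
        raise ValueError("observed series has zero variance; NSD undefined")
    diff = o - m
    return FitMetrics(
        mbe=float(np.mean(diff)),
        mae=float(np.mean(np.abs(diff))),
        rmse=float(np.sqrt(np.mean(diff ** 2))),
        nsd=float(np.std(m, ddof=1) / sd_o),
    )


def metrics_across_models(obs: pd.Series,
                          corrected_per_model: Sequence[pd.Series]) -> FitMetrics:
    """Arithmetic mean of each fit statistic over ensemble members."""
    if len(corrected_per_model) < 1:
        raise ValueError("need at least one model")
    per = [compute_metrics(obs, m) for m in corrected_per_model]
    return FitMetrics(
        mbe=float(np.mean([p.mbe for p in per])),
        mae=float(np.mean([p.mae for p in per])),
        rmse=float(np.mean([p.rmse for p in per])),
        nsd=float(np.mean([p.nsd for p in per])),
    )


def metrics_table(obs: pd.Series,
                  corrected_per_model: dict[str, pd.Series]) -> pd.DataFrame:
    """One row of fit statistics per model plus an ``average`` row."""
    rows = {}
    for name, series in corrected_per_model.items():
        m = compute_metrics(obs, series)
        rows[name] = [m.mbe, m.mae, m.rmse, m.nsd]
    avg = metrics_across_models(obs, list(corrected_per_model.values()))
    rows["average"] = [avg.mbe, avg.mae, avg.rmse, avg.nsd]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["mbe", "mae", "rmse", "nsd"])


def _warm_period_subset(series: pd.Series, period: tuple[str, str]) -> pd.Series:
    sub = series[(series.index >= pd.Timestamp(period[0]))
                 & (series.index <= pd.Timestamp(period[1]))]
    sub = sub[sub.index.month.isin(WARM_MONTHS)].dropna()
    if sub.empty:
        raise ValueError(f"model does not cover warm-season days of {period}")
    return sub


def period_mean(series: pd.Series, period: tuple[str, str]) -> float:
    """Default within-model statistic: mean of warm-season daily values."""
    return float(_warm_period_subset(series, period).mean())


@dataclass(frozen=True)
class EnsembleSpread:
    statistic: str
    sd_across_models: float


def between_model_sd(series_per_model: Sequence[pd.Series],
                     period: tuple[str, str],
                     statistic: Callable[[pd.Series, tuple], float] | str = "period_mean",
                     ) -> EnsembleSpread:
    """Sample SD across ensemble members of a within-model summary.

    ``statistic`` may be ``"period_mean"`` (warm-season mean of daily
    values), ``"daily_sd"`` (cross-model SD computed day by day, averaged
    over days -- the alternative reading of averaging first across days),
    or a callable ``(series, period) -> float``.
    """
    if len(series_per_model) < 2:
        raise ValueError("between-model SD needs at least 2 models")
    if statistic == "daily_sd":
        subs = [_warm_period_subset(s, period) for s in series_per_model]
        mat = pd.concat(subs, axis=1, join="inner")
        if mat.empty:
            raise ValueError("models share no warm-season days in the period")
        per_day_sd = mat.std(axis=1, ddof=1)
        return EnsembleSpread("daily_sd", float(per_day_sd.mean()))
    fn = period_mean if statistic == "period_mean" else statistic
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    stats = np.array([fn(s, period) for s in series_per_model])
    return EnsembleSpread(name, float(np.std(stats, ddof=1)))
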