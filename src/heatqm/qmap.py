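"""Quantile-mapping bias correction of climate-model temperature.

Five transfer-function families are implemented behind one abstraction:

* ``normal``    -- Gaussian CDF composition, closed form
  g(x) = mu_o + (sigma_o / sigma_m) * (x - mu_m);
* ``empirical`` -- nonparametric mapping between the empirical quantile
  tables of observations and model hindcast on a regular level grid, with
  linear interpolation between grid rows;
* ``robust``    -- empirical mapping smoothed by local linear least squares
  on the k nearest quantile-quantile pairs at each level, averaged over
  bootstrap resamples of the raw daily data;
* ``linear``    -- ordinary least squares of observed on model quantiles,
  g(x) = a + b*x everywhere;
* ``qdm``       -- quantile delta mapping, which maps each projection-day
  value through its level in the *projection-period* model distribution and
  adds back the model-projected change in that quantile, so absolute
  climate-change signals pass through the correction.

All methods may be fitted within calendar seasons (DJF/MAM/JJA/SON) and
reassembled in date order, which is how they are applied in practice to
remove seasonality from the calibration.

Extrapolation: table-based methods (empirical, robust) use a constant-offset
rule beyond the calibration range -- the correction at the nearest table
boundary is applied unchanged -- which keeps behavior bounded on
unprecedented future extremes.  Normal and linear methods extrapolate by
their functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import warnings

import numpy as np
import pandas as pd

from .series import daily_series, season_labels, SEASONS

Method = Literal["normal", "empirical", "robust", "linear", "qdm"]

METHODS: tuple[str, ...] = ("normal", "empirical", "robust", "linear", "qdm")


def quantile_grid(step: float = 0.01) -> np.ndarray:
    """Regularly spaced quantile levels 0, step, ..., 1 (always includes 0 and 1)."""
    if not 0 < step <= 0.5:
        raise ValueError("grid step must be in (0, 0.5]")
    n = int(round(1.0 / step))
    grid = np.linspace(0.0, 1.0, n + 1)
    return grid


def _clean(series: pd.Series, min_points: int = 2) -> np.ndarray:
    vals = np.asarray(series, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_points:
        raise ValueError(f"need at least {min_points} non-missing values, got {len(vals)}")
    return vals


def empirical_quantiles(series: pd.Series, grid: np.ndarray) -> np.ndarray:
    """Sample quantiles on the level grid (linear interpolation of order
    statistics, the default continuous-sample estimator).

    Level 0 maps to the sample minimum and level 1 to the maximum, so the
    table always brackets the calibration data.
    """
    vals = _clean(series)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid levels must be strictly increasing")
    if grid[0] != 0.0 or grid[-1] != 1.0:
        raise ValueError("grid must include levels 0 and 1")
    return np.quantile(vals, grid, method="linear")


@dataclass
class TransferFunction:
    """A fitted season-specific mapping from model values to corrected values.

    ``params`` is method-specific:

    * normal: ``obs_mean, obs_sd, model_mean, model_sd``
    * linear: ``intercept, slope``
    * empirical / robust: ``levels, model_q, corrected`` (paired table)
    * qdm: ``levels, obs_q, model_hist_q`` plus a projection-period table
      fitted at apply time (``qdm_correct``)
    """

    method: str
    params: dict = field(default_factory=dict)
    season: str | None = None
    extrapolation_rule: str = "constant_offset"

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.method == "normal":
            p = self.params
            return p["obs_mean"] + (p["obs_sd"] / p["model_sd"]) * (x - p["model_mean"])
        if self.method == "linear":
            return self.params["intercept"] + self.params["slope"] * x
        if self.method in ("empirical", "robust"):
            return _table_transform(x, self.params["model_q"], self.params["corrected"])
        raise ValueError(f"transfer function of method {self.method!r} is not "
                         "applied elementwise (use qdm_correct)")

    def table(self) -> pd.DataFrame:
        """Quantile table view (``tau, model_q, corrected``) for inspection."""
        if self.method in ("empirical", "robust"):
            return pd.DataFrame({"tau": self.params["levels"],
                                 "model_q": self.params["model_q"],
                                 "corrected": self.params["corrected"]})
        raise ValueError("only table-based methods export a quantile table")


def _table_transform(x: np.ndarray, model_q: np.ndarray,
                     corrected: np.ndarray) -> np.ndarray:
    """Piecewise-linear table lookup with constant-offset extrapolation.

    Inside [model_q.min, model_q.max] the corrected value interpolates the
    table; outside, the boundary correction (corrected - model_q at the
    nearest end) is added to x unchanged.
    """
    out = np.interp(x, model_q, corrected)
    lo, hi = model_q[0], model_q[-1]
    below = x < lo
    above = x > hi
    if np.any(below):
        out = np.where(below, x + (corrected[0] - lo), out)
    if np.any(above):
        out = np.where(above, x + (corrected[-1] - hi), out)
    return out


def _ecdf_level(values_on_grid: np.ndarray, grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Empirical CDF level of x via inverse interpolation of a quantile table."""
    return np.interp(x, values_on_grid, grid)


def fit_normal_qm(obs_hist: pd.Series, model_hist: pd.Series,
                  season: str | None = None) -> TransferFunction:
    """Gaussian quantile mapping: compose the model's Normal CDF with the
    inverse Normal CDF of the observations, which reduces to a location-scale
    transform."""
    o = _clean(obs_hist)
    m = _clean(model_hist)
    sd_m = float(np.std(m, ddof=1))
    if sd_m <= 0:
        raise ValueError("model historical series has zero standard deviation")
    return TransferFunction(
        "normal",
        {"obs_mean": float(np.mean(o)), "obs_sd": float(np.std(o, ddof=1)),
         "model_mean": float(np.mean(m)), "model_sd": sd_m},
        season=season, extrapolation_rule="functional_form",
    )


def fit_empirical_qm(obs_hist: pd.Series, model_hist: pd.Series,
                     grid: np.ndarray | None = None,
                     season: str | None = None) -> TransferFunction:
    """Nonparametric quantile mapping on a regular level grid."""
    grid = quantile_grid() if grid is None else np.asarray(grid, dtype=float)
    if not obs_hist.index.intersection(model_hist.index).size:
        warnings.warn("observed and model historical series do not overlap in time",
                      stacklevel=2)
    obs_q = empirical_quantiles(obs_hist, grid)
    model_q = empirical_quantiles(model_hist, grid)
    return TransferFunction(
        "empirical",
        {"levels": grid, "model_q": model_q, "corrected": obs_q},
        season=season,
    )


def fit_linear_qm(obs_hist: pd.Series, model_hist: pd.Series,
                  grid: np.ndarray | None = None,
                  season: str | None = None) -> TransferFunction:
    """Linear quantile mapping: OLS of the observed on the model quantile
    function, g(x) = a + b*x everywhere.

    The regression uses the quantile functions at full resolution -- every
    paired order statistic when the series have equal length, otherwise
    quantiles at the midpoint levels (i - 1/2)/n of the shorter series.
    Fitting through the complete order statistics makes the line pass
    through the sample means, so applying the transfer back to the
    calibration data leaves zero mean bias by construction; a coarse grid
    would leak its endpoint noise into a and b.
    """
    o = np.sort(_clean(obs_hist))
    m = np.sort(_clean(model_hist))
    if np.ptp(m) == 0:
        raise ValueError("model quantiles are constant; linear fit is degenerate")
    if len(o) != len(m):
        n = min(len(o), len(m))
        levels = (np.arange(n) + 0.5) / n
        o = np.quantile(o, levels, method="linear")
        m = np.quantile(m, levels, method="linear")
    slope, intercept = np.polyfit(m, o, 1)
    return TransferFunction(
        "linear", {"intercept": float(intercept), "slope": float(slope)},
        season=season, extrapolation_rule="functional_form",
    )


def fit_robust_qm(obs_hist: pd.Series, model_hist: pd.Series,
                  grid: np.ndarray | None = None, k_nearest: int = 10,
                  n_boot: int = 10, seed: int = 0,
                  season: str | None = None) -> TransferFunction:
    """Robust quantile mapping: local linear least squares on the
    quantile-quantile pairs, bootstrap-averaged.

    For each grid level the k nearest quantile-quantile pairs (by model
    quantile value, ties toward the lower level) define a local line whose
    prediction at the full-sample model quantile is the corrected value.
    The procedure is replicated on ``n_boot`` bootstrap resamples of the
    quantile-quantile table rows (with replacement) and the mean table over
    replicates is kept; resampling the table rather than the raw days keeps
    the bootstrap average centered on the full-sample mapping, so the
    corrected hindcast stays mean-unbiased.  The corrected column is made
    non-decreasing by a running maximum so the fitted transfer is monotone.
    """
    grid = quantile_grid() if grid is None else np.asarray(grid, dtype=float)
    if k_nearest < 2:
        raise ValueError("k_nearest must be >= 2")
    if k_nearest > len(grid):
        raise ValueError(f"k_nearest ({k_nearest}) exceeds grid size ({len(grid)})")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    obs_q_full = empirical_quantiles(obs_hist, grid)
    model_q_full = empirical_quantiles(model_hist, grid)

    rng = np.random.default_rng(seed)
    n = len(grid)
    preds = np.zeros((n_boot, n))
    for b in range(n_boot):
        rows = np.sort(rng.integers(0, n, size=n))
        preds[b] = _local_linear_predict(model_q_full[rows], obs_q_full[rows],
                                         model_q_full, k_nearest)
    corrected = preds.mean(axis=0)
    corrected = np.maximum.accumulate(corrected)

    return TransferFunction(
        "robust",
        {"levels": grid, "model_q": model_q_full, "corrected": corrected},
        season=season,
    )


def _local_linear_predict(mq: np.ndarray, oq: np.ndarray,
                          x_eval: np.ndarray, k: int) -> np.ndarray:
    """At each grid position, fit y ~ a + b*x through the k nearest
    (mq, oq) pairs (nearest by |mq - mq[i]|, ties to lower level) and
    predict at x_eval[i]."""
    n = len(mq)
    # distance matrix grid-point x grid-point; stable sort breaks ties
    # toward the lower level index
    order = np.argsort(np.abs(mq[None, :] - mq[:, None]), axis=1, kind="stable")
    nearest = order[:, :k]
    xs = mq[nearest]           # (n, k)
    ys = oq[nearest]
    xbar = xs.mean(axis=1)
    ybar = ys.mean(axis=1)
    sxx = ((xs - xbar[:, None]) ** 2).sum(axis=1)
    sxy = ((xs - xbar[:, None]) * (ys - ybar[:, None])).sum(axis=1)
    # degenerate neighborhoods (all duplicated quantiles) fall back to the mean
    slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    return ybar + slope * (x_eval - xbar)


def qdm_correct(obs_hist: pd.Series, model_hist: pd.Series,
                model_proj: pd.Series,
                grid: np.ndarray | None = None,
                return_components: bool = False):
    """Quantile delta mapping of a projection series.

    For each projection day with value x: find its level tau in the
    projection-period model distribution; the corrected value is the
    observed historical quantile at tau plus the model-projected change
    Delta(t) = x - F_mh^{-1}(tau).  The delta identity

        corrected - F_oh^{-1}(tau) == Delta(t)

    holds exactly by construction, so absolute changes in quantiles survive
    the correction.  With ``return_components=True`` a DataFrame with the
    ``corrected`` values and their two addends ``mapped_obs`` (the observed
    quantile at tau) and ``delta`` is returned, so the identity can be
    audited at full precision.

    By default the level grid is taken at full resolution -- one level per
    order statistic of the longest input series -- so each quantile table
    represents its empirical quantile function exactly, the convention of
    standard QDM implementations; pass an explicit (coarser) grid to share
    levels with the table-based methods.
    """
    if grid is None:
        n = max(len(_clean(obs_hist)), len(_clean(model_hist)),
                len(_clean(model_proj)))
        grid = np.linspace(0.0, 1.0, n)
    else:
        grid = np.asarray(grid, dtype=float)
    obs_q = empirical_quantiles(obs_hist, grid)
    mh_q = empirical_quantiles(model_hist, grid)
    mp_q = empirical_quantiles(model_proj, grid)
    if np.ptp(mp_q) == 0:
        raise ValueError("projection distribution is degenerate")

    x = model_proj.to_numpy(dtype=float)
    out = np.full_like(x, np.nan)
    mapped = np.full_like(x, np.nan)
    delta_full = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    tau = _ecdf_level(mp_q, grid, x[ok])
    delta = x[ok] - np.interp(tau, grid, mh_q)
    mapped[ok] = np.interp(tau, grid, obs_q)
    delta_full[ok] = delta
    out[ok] = mapped[ok] + delta
    if return_components:
        return pd.DataFrame({"corrected": out, "mapped_obs": mapped,
                             "delta": delta_full}, index=model_proj.index)
    return daily_series(model_proj.index, out, name="tmin_qdm")


def apply_transfer(tf: TransferFunction, series: pd.Series) -> pd.Series:
    """Elementwise application of a fitted transfer; dates unchanged,
    missing values propagate."""
    x = series.to_numpy(dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    out[ok] = tf(x[ok])
    return daily_series(series.index, out, name=series.name)


def fit_transfer(method: str, obs_hist: pd.Series, model_hist: pd.Series,
                 grid: np.ndarray | None = None, *, k_nearest: int = 10,
                 n_boot: int = 10, seed: int = 0,
                 season: str | None = None) -> TransferFunction:
    """Dispatch to the per-method fitters (QDM has no standalone transfer;
    see ``qdm_correct``)."""
    if method == "normal":
        return fit_normal_qm(obs_hist, model_hist, season=season)
    if method == "empirical":
        return fit_empirical_qm(obs_hist, model_hist, grid, season=season)
    if method == "linear":
        return fit_linear_qm(obs_hist, model_hist, grid, season=season)
    if method == "robust":
        return fit_robust_qm(obs_hist, model_hist, grid, k_nearest=k_nearest,
                             n_boot=n_boot, seed=seed, season=season)
    raise ValueError(f"unknown method {method!r}")


def seasonal_fit_apply(method: str, obs_hist: pd.Series, model_hist: pd.Series,
                       model_target: pd.Series,
                       grid: np.ndarray | None = None, *, seasonal: bool = True,
                       k_nearest: int = 10, n_boot: int = 10,
                       seed: int = 0) -> pd.Series:
    """Fit the chosen method per calendar season on the historical pair and
    correct the target series, reassembled in date order.

    With ``seasonal=False`` a single all-year transfer is used.  For QDM the
    target must be the projection series itself, since its distribution
    enters the transfer.
    """
    if not seasonal:
        if method == "qdm":
            return qdm_correct(obs_hist, model_hist, model_target, grid)
        tf = fit_transfer(method, obs_hist, model_hist, grid,
                          k_nearest=k_nearest, n_boot=n_boot, seed=seed)
        return apply_transfer(tf, model_target)

    obs_seasons = season_labels(obs_hist.index)
    mod_seasons = season_labels(model_hist.index)
    tgt_seasons = season_labels(model_target.index)
    out = pd.Series(np.nan, index=model_target.index, name=model_target.name)
    for s in SEASONS:
        tgt_mask = tgt_seasons == s
        if not tgt_mask.any():
            continue
        o = obs_hist[obs_seasons == s]
        m = model_hist[mod_seasons == s]
        if len(o.dropna()) < 2 or len(m.dropna()) < 2:
            raise ValueError(f"season {s} absent from historical data")
        t = model_target[tgt_mask]
        if method == "qdm":
            corrected = qdm_correct(o, m, t, grid)
        else:
            tf = fit_transfer(method, o, m, grid, k_nearest=k_nearest,
                              n_boot=n_boot, seed=seed, season=s)
            corrected = apply_transfer(tf, t)
        out[tgt_mask] = corrected.to_numpy()
    return out
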