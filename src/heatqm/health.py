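"""Quasi-Poisson time-series model of temperature and daily ED visits.

The mean daily count mu_t is modeled on the log scale as

    log mu_t = alpha_0 + f(x_t) + h(t) + day-of-week + holiday [+ dew point]

where x_t is the trailing 3-day moving average of daily minimum temperature
(same day, lag 1, lag 2), f is a natural cubic spline (default 3 df), and
h(t) is a natural cubic spline of calendar time with monthly knots that
absorbs long-term and seasonal trends.  The analysis is restricted to the
warm season (May-September) after the moving average is computed, so
early-May exposures use late-April temperatures.

Overdispersion is handled quasi-likelihood style: coefficients are the
Poisson MLE, and the covariance is the Poisson covariance scaled by the
Pearson chi-square dispersion estimate.

The fitted exposure-response is summarized as the log relative risk
theta(x) = f(x) - f(x0) relative to a reference exposure x0: the minimum
observed exposure when the association is strictly increasing over the
observed range, otherwise the minimum-risk exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


import numpy as np
import pandas as pd
import statsmodels.api as sm

from .series import WARM_MONTHS
from .splines import NaturalSpline
from .synthdata import moving_average  # shared trailing-window definition

logger = logging.getLogger(__name__)

__all__ = ["HealthModelSpec", "HealthModelFit", "ExposureResponse",
           "moving_average", "build_design", "fit_quasipoisson", "extract_erf"]


@dataclass(frozen=True)
class HealthModelSpec:
    """Model-specification knobs.

    ``time_knot_spacing``: ``"monthly"`` places interior time-spline knots at
    the first day of every analyzed calendar month after the first; an
    integer k places k equally spaced interior knots within each analyzed
    warm season (the sensitivity settings use 4, 5 or 7).
    """

    exposure_df: int = 3
    time_knot_spacing: str | int = "monthly"
    lag_window: int = 3
    use_dow: bool = True
    use_holidays: bool = True
    use_dewpoint: bool = False
    dewpoint_df: int = 3

    def __post_init__(self):
        if self.exposure_df < 2:
            raise ValueError("exposure_df must be >= 2")
        if self.lag_window < 1:
            raise ValueError("lag_window must be >= 1")


@dataclass
class Design:
    """Design matrix plus the metadata needed to reconstruct f(x)."""

    X: pd.DataFrame
    exposure_basis: NaturalSpline
    exposure_cols: list[str]
    exposure: pd.Series            # moving-average exposure on analyzed days
    spec: HealthModelSpec


def _time_knots(index: pd.DatetimeIndex, spacing: str | int) -> np.ndarray:
    """Interior knots for the time spline, as day ordinals."""
    t = index.to_julian_date().to_numpy()
    if spacing == "monthly":
        months = pd.PeriodIndex(index, freq="M").unique()
        knots = [pd.Timestamp(m.start_time) for m in months]
        # knots strictly inside the span
        knots = [k.to_julian_date() for k in knots
                 if t.min() < k.to_julian_date() < t.max()]
        return np.asarray(knots, dtype=float)
    k = int(spacing)
    knots = []
    for year in np.unique(index.year):
        ty = t[index.year == year]
        if len(ty) < 2:
            continue
        qs = np.linspace(0, 1, k + 2)[1:-1]
        knots.extend(ty.min() + qs * (ty.max() - ty.min()))
    return np.asarray(sorted(knots), dtype=float)


def build_design(exposure: pd.Series, counts_dates: pd.DatetimeIndex,
                 spec: HealthModelSpec,
                 covariates: pd.DataFrame | None = None) -> Design:
    """Assemble the regression design on the analyzed (warm-season) days.

    ``exposure`` is the already-moving-averaged temperature covering at
    least ``counts_dates``; ``covariates`` may supply ``holiday`` (0/1) and
    ``dewpoint`` columns indexed by date.
    """
    idx = pd.DatetimeIndex(counts_dates)
    idx = idx[idx.month.isin(WARM_MONTHS)]
    x = exposure.reindex(idx)
    if x.isna().any():
        missing = idx[x.isna()]
        raise ValueError(f"exposure missing for {len(missing)} analyzed days "
                         f"(first: {missing[0].date()})")

    cols: dict[str, np.ndarray] = {"const": np.ones(len(idx))}

    exp_basis = NaturalSpline.from_data(x.to_numpy(), spec.exposure_df)
    bx = exp_basis.basis(x.to_numpy())
    exposure_cols = [f"exp_ns{j + 1}" for j in range(bx.shape[1])]
    for j, name in enumerate(exposure_cols):
        cols[name] = bx[:, j]

    t = idx.to_julian_date().to_numpy()
    tk = _time_knots(idx, spec.time_knot_spacing)
    time_basis = NaturalSpline(tk, (t.min(), t.max()))
    bt = time_basis.basis(t)
    for j in range(bt.shape[1]):
        cols[f"time_ns{j + 1}"] = bt[:, j]

    if spec.use_dow:
        dow = idx.dayofweek
        for d in range(1, 7):  # Monday is the reference level
            cols[f"dow_{d}"] = (dow == d).astype(float)

    if spec.use_holidays:
        hol = np.zeros(len(idx))
        if covariates is not None and "holiday" in covariates:
            hol = covariates["holiday"].reindex(idx).fillna(0).to_numpy(dtype=float)
        cols["holiday"] = hol

    if spec.use_dewpoint:
        if covariates is None or "dewpoint" not in covariates:
            raise ValueError("dewpoint spline requested but no dewpoint covariate supplied")
        dp = covariates["dewpoint"].reindex(idx)
        if dp.isna().any():
            raise ValueError("dewpoint covariate missing on analyzed days")
        dp_basis = NaturalSpline.from_data(dp.to_numpy(), spec.dewpoint_df)
        bd = dp_basis.basis(dp.to_numpy())
        for j in range(bd.shape[1]):
            cols[f"dewpoint_ns{j + 1}"] = bd[:, j]

    X = pd.DataFrame(cols, index=idx)
    # drop all-zero indicator columns (e.g. no holidays in the sample)
    degenerate = [c for c in X.columns if c != "const" and X[c].abs().sum() == 0]
    X = X.drop(columns=degenerate)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        keep: list[str] = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")

    return Design(X=X, exposure_basis=exp_basis, exposure_cols=exposure_cols,
                  exposure=x, spec=spec)


@dataclass
class HealthModelFit:
    coefficients: pd.Series
    covariance: pd.DataFrame     # quasi-Poisson: dispersion x inverse information
    dispersion: float
    design: Design


def fit_quasipoisson(counts: pd.Series, design: Design) -> HealthModelFit:
    """Poisson MLE with Pearson-dispersion-scaled covariance."""
    y = counts.reindex(design.X.index)
    if y.isna().any():
        raise ValueError("counts missing on analyzed days")
    yv = y.to_numpy(dtype=float)
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("counts must be nonnegative integers")
    model = sm.GLM(yv, design.X.to_numpy(), family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2", maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely here
        raise RuntimeError(f"quasi-Poisson fit did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"quasi-Poisson fit did not converge after "
                           f"{res.fit_history['iteration']} iterations; "
                           f"deviance trace: {res.fit_history['deviance'][-5:]}")
    names = list(design.X.columns)
    coef = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return HealthModelFit(coefficients=coef, covariance=cov,
                          dispersion=float(res.scale), design=design)


@dataclass
class ExposureResponse:
    """Log relative risk theta(x) = f(x) - f(x0) with its uncertainty.

    ``beta`` and ``cov`` are the exposure-spline coefficient subvector and
    covariance block from the quasi-Poisson fit.
    """

    basis: NaturalSpline
    beta: np.ndarray
    cov: np.ndarray
    reference: float
    observed_range: tuple[float, float]
    monotone_increasing: bool = True

    def _contrast(self, x) -> np.ndarray:
        return self.basis.basis(x) - self.basis.basis([self.reference])

    def theta(self, x) -> np.ndarray:
        """Log relative risk at exposure x relative to the reference."""
        return self._contrast(x) @ self.beta

    def se(self, x) -> np.ndarray:
        d = self._contrast(x)
        return np.sqrt(np.einsum("ij,jk,ik->i", d, self.cov, d))

    def theta_draws(self, x, beta_draws: np.ndarray) -> np.ndarray:
        """theta(x) under sampled coefficient vectors; shape (len(x), n_draws)."""
        return self._contrast(x) @ beta_draws.T

    def curve(self, x) -> pd.DataFrame:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return pd.DataFrame({"x": x, "theta": self.theta(x), "se": self.se(x)})


def extract_erf(fit: HealthModelFit, n_grid: int = 200) -> ExposureResponse:
    """Exposure-response summary from a fitted health model.

    The reference exposure is the minimum observed moving-average exposure
    when f is strictly increasing on a ``n_grid``-point grid over the
    observed range; for a U-shaped (or otherwise non-monotone) association
    the minimum-risk exposure on the grid is used instead.
    """
    names = fit.design.exposure_cols
    beta = fit.coefficients[names].to_numpy()
    cov = fit.covariance.loc[names, names].to_numpy()
    basis = fit.design.exposure_basis
    xobs = fit.design.exposure.to_numpy()
    lo, hi = float(xobs.min()), float(xobs.max())
    grid = np.linspace(lo, hi, n_grid)
    f = basis.basis(grid) @ beta
    increasing = bool(np.all(np.diff(f) > 0))
    if increasing:
        ref = lo
    else:
        ref = float(grid[np.argmin(f)])
        logger.info("exposure-response not strictly increasing; "
                    "reference set to minimum-risk exposure %.2f", ref)
    return ExposureResponse(basis=basis, beta=beta, cov=cov, reference=ref,
                            observed_range=(lo, hi), monotone_increasing=increasing)
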