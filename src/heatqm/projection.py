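"""Temperature-attributable ED visits, historically and under projection.

For each historical warm-season day with count n_t and exposure x_t, the
attributable number is

    AN_H(t) = n_t * (1 - exp(-theta(x_t)))

and for a projection day with bias-corrected exposure xhat_t, paired with a
historical baseline day,

    AN_P(t) = (n_t - AN_H(t)) * (exp(theta(xhat_t)) - 1)

where n_t - AN_H(t) is the baseline (temperature-free) visit count.  The two
forms agree when the same theta applies: n(1-e^-theta) = (n-AN_H)(e^theta-1).

Uncertainty is quantified by Monte Carlo: spline coefficient vectors are
drawn from a multivariate Normal centered at the quasi-Poisson estimates
with the dispersion-scaled covariance, and the annual excess (mean over
projection years of the May-September sum of AN_P, with AN_H recomputed
per draw) is summarized by its median and 2.5th/97.5th percentiles.  The
same coefficient draws are reused for every ensemble member, so
between-model differences reflect exposure alone; ensemble summaries either
average members within each draw ("average") or pool all members' draws
("pooled", which carries between-model spread into the interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .health import ExposureResponse
from .series import align, warm_season

logger = logging.getLogger(__name__)

_MC_CHUNK = 250  # coefficient draws evaluated per block to bound memory


def attributable_historical(counts: pd.Series, erf: ExposureResponse,
                            exposure: pd.Series) -> pd.Series:
    """Daily historical attributable numbers AN_H(t) = n_t (1 - e^{-theta})."""
    align(counts, exposure)
    theta = erf.theta(exposure.to_numpy())
    an = counts.to_numpy(dtype=float) * (1.0 - np.exp(-theta))
    return pd.Series(an, index=counts.index, name="an_hist")


def pair_days(future_index: pd.DatetimeIndex,
              hist_index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Match each projection day to a historical day with the same
    month/day (Feb 29 -> Feb 28), cycling the historical years across the
    projection years."""
    hist_years = np.sort(np.unique(hist_index.year))
    n_hist = len(hist_years)
    fut_year0 = int(future_index.year.min())
    hist_set = set(hist_index)
    paired = []
    for ts in future_index:
        hy = int(hist_years[(ts.year - fut_year0) % n_hist])
        month, day = ts.month, ts.day
        if month == 2 and day == 29:
            day = 28
        cand = pd.Timestamp(year=hy, month=month, day=day)
        if cand not in hist_set:
            raise ValueError(f"projection day {ts.date()} has no paired "
                             f"historical day {cand.date()}")
        paired.append(cand)
    return pd.DatetimeIndex(paired)


def attributable_projected(counts_hist: pd.Series, an_hist: pd.Series,
                           erf: ExposureResponse, future_exposure: pd.Series,
                           day_pairing: str = "calendar") -> pd.Series:
    """Daily projected attributable numbers using paired historical baselines.

    ``day_pairing``: ``"calendar"`` pairs each projection day to the same
    month/day of a cycled historical year; ``"month_mean"`` uses the mean
    baseline over all historical days of the same calendar month.
    """
    align(counts_hist, an_hist)
    baseline_hist = counts_hist - an_hist
    fut_idx = future_exposure.index
    if day_pairing == "calendar":
        paired = pair_days(fut_idx, counts_hist.index)
        baseline = baseline_hist.loc[paired].to_numpy()
    elif day_pairing == "month_mean":
        by_month = baseline_hist.groupby(baseline_hist.index.month).mean()
        baseline = by_month.loc[fut_idx.month].to_numpy()
    else:
        raise ValueError(f"unknown day_pairing {day_pairing!r}")
    theta = erf.theta(future_exposure.to_numpy())
    an = baseline * (np.exp(theta) - 1.0)
    return pd.Series(an, index=fut_idx, name="an_proj")


@dataclass
class MCDraws:
    """Per-draw annual excess visits, one vector per ensemble member."""

    annual_excess: dict[str, np.ndarray]
    n_draws: int
    seed: int

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("need at least 2 Monte Carlo draws")
        for name, v in self.annual_excess.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws for model {name}")


def draw_coefficients(erf: ExposureResponse, n_draws: int,
                      seed: int) -> np.ndarray:
    """Sample exposure-spline coefficient vectors from their asymptotic
    multivariate Normal; shape (n_draws, p)."""
    cov = np.asarray(erf.cov, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("coefficient covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(erf.beta, cov, size=n_draws, method="svd")


def monte_carlo(erf: ExposureResponse, counts_hist: pd.Series,
                exposure_hist: pd.Series,
                future_exposure_by_model: dict[str, pd.Series],
                n_draws: int = 5000, seed: int = 0,
                day_pairing: str = "calendar") -> MCDraws:
    """Per-draw annual excess warm-season visits for each ensemble member.

    For every coefficient draw, historical AN (hence baselines) and
    projected AN are recomputed jointly; the annual excess is the mean over
    projection years of the May-September sum of daily AN_P.  All members
    share the same coefficient draws.
    """
    align(counts_hist, exposure_hist)
    draws = draw_coefficients(erf, n_draws, seed)
    n_hist = counts_hist.to_numpy(dtype=float)
    x_hist = exposure_hist.to_numpy()

    out: dict[str, np.ndarray] = {}
    for name, fut in future_exposure_by_model.items():
        fut = warm_season(fut.dropna())
        lo, hi = erf.observed_range
        frac_out = float(np.mean((fut.to_numpy() < lo) | (fut.to_numpy() > hi)))
        if frac_out:
            logger.info("model %s: %.1f%% of future exposures beyond the "
                        "observed range (linear-tail extrapolation)", name,
                        100 * frac_out)
        paired = pair_days(fut.index, counts_hist.index)
        pos = counts_hist.index.get_indexer(paired)
        years = fut.index.year.to_numpy()
        year_ids, year_inv = np.unique(years, return_inverse=True)
        n_paired = n_hist[pos]

        excess = np.empty(n_draws)
        for start in range(0, n_draws, _MC_CHUNK):
            block = draws[start:start + _MC_CHUNK]
            th_h = erf.theta_draws(x_hist, block)       # (hist days, b)
            th_p = erf.theta_draws(fut.to_numpy(), block)
            baseline = n_paired[:, None] * np.exp(-th_h[pos])
            an_p = baseline * (np.exp(th_p) - 1.0)
            annual = np.zeros((len(year_ids), block.shape[0]))
            np.add.at(annual, year_inv, an_p)
            excess[start:start + _MC_CHUNK] = annual.mean(axis=0)
        out[name] = excess

    return MCDraws(annual_excess=out, n_draws=n_draws, seed=seed)


@dataclass(frozen=True)
class ProjectionSummary:
    point: float     # median over draws, visits/year
    lower: float     # 2.5th percentile
    upper: float     # 97.5th percentile
    scope: str

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("summary must satisfy lower <= point <= upper")


def summarize(draws: np.ndarray, scope: str = "single-model") -> ProjectionSummary:
    """Median and central 95% interval of per-draw annual excess visits
    (linear interpolation of order statistics)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws to summarize")
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return ProjectionSummary(point=float(med), lower=float(lo), upper=float(hi),
                             scope=scope)


def _stacked(mc: MCDraws) -> np.ndarray:
    mat = np.vstack(list(mc.annual_excess.values()))
    if np.unique([len(v) for v in mc.annual_excess.values()]).size != 1:
        raise ValueError("ensemble members must share the draw count")
    return mat


def ensemble_average(mc: MCDraws) -> ProjectionSummary:
    """Across-model mean within each shared draw, then summarize; ignores
    between-model spread."""
    return summarize(_stacked(mc).mean(axis=0), scope="ensemble-average")


def ensemble_pooled(mc: MCDraws) -> ProjectionSummary:
    """Pool all members' draws, then summarize; carries between-model spread
    into the interval."""
    return summarize(_stacked(mc).ravel(), scope="ensemble-pooled")


def summary_table(mc: MCDraws) -> pd.DataFrame:
    """Per-model plus both ensemble summaries (``scope,point,lower,upper``)."""
    rows = []
    for name, v in mc.annual_excess.items():
        s = summarize(v, scope=name)
        rows.append((s.scope, s.point, s.lower, s.upper))
    for s in (ensemble_average(mc), ensemble_pooled(mc)):
        rows.append((s.scope, s.point, s.lower, s.upper))
    return pd.DataFrame(rows, columns=["scope", "point", "lower", "upper"])
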