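"""Transfer-function oracles: closed forms, identity mappings, delta
preservation, extrapolation rules, and monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heatqm as hq
from heatqm import qmap
from heatqm.series import daily_series


def _series(values, start="2000-01-01"):
    return daily_series(pd.date_range(start, periods=len(values)), values)


def _normal_series(mu, sd, n, seed, start="2000-01-01"):
    rng = np.random.default_rng(seed)
    return _series(mu + sd * rng.standard_normal(n), start)


class TestQuantileGrid:
    def test_default_grid_is_percent_steps(self):
        g = qmap.quantile_grid()
        assert len(g) == 101 and g[0] == 0.0 and g[-1] == 1.0
        assert np.allclose(np.diff(g), 0.01)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            qmap.quantile_grid(0.0)


class TestEmpiricalQuantiles:
    def test_order_statistics(self):
        q = qmap.empirical_quantiles(_series([1, 2, 3, 4, 5]),
                                     np.array([0.0, 0.5, 1.0]))
        assert list(q) == [1.0, 3.0, 5.0]

    def test_constant_series(self):
        q = qmap.empirical_quantiles(_series([7, 7, 7]), qmap.quantile_grid())
        assert (q == 7.0).all()

    def test_monte_carlo_matches_closed_form(self):
        s = _normal_series(0, 1, 10_000, seed=0)
        q = qmap.empirical_quantiles(s, np.array([0.0, 0.975, 1.0]))
        assert q[1] == pytest.approx(1.959964, abs=0.06)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            qmap.empirical_quantiles(_series([1.0]), qmap.quantile_grid())
        with pytest.raises(ValueError, match="include levels 0 and 1"):
            qmap.empirical_quantiles(_series([1, 2, 3]), np.array([0.1, 0.9]))


class TestNormalMapping:
    def test_closed_form_values(self):
        obs = _normal_series(20, 5, 50_000, seed=1)
        mod = _normal_series(18, 4, 50_000, seed=2)
        tf = qmap.fit_normal_qm(obs, mod)
        # the Phi-composition collapses to mu_o + (sigma_o/sigma_m)(x - mu_m)
        assert tf(18.0) == pytest.approx(20.0, abs=0.1)
        assert tf(22.0) == pytest.approx(25.0, abs=0.2)
        p = tf.params
        x = np.linspace(-10, 40, 7)
        expected = p["obs_mean"] + p["obs_sd"] / p["model_sd"] * (x - p["model_mean"])
        assert np.allclose(tf(x), expected, atol=1e-12)

    def test_identical_moments_give_identity(self):
        s = _normal_series(10, 3, 500, seed=3)
        tf = qmap.fit_normal_qm(s, s)
        x = np.linspace(0, 20, 11)
        assert np.allclose(tf(x), x, atol=1e-12)

    def test_zero_model_sd_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            qmap.fit_normal_qm(_series([1, 2, 3]), _series([5, 5, 5]))


class TestEmpiricalQM:
    def test_identity_when_model_equals_obs(self, obs):
        tf = qmap.fit_empirical_qm(obs, obs)
        x = np.linspace(obs.min(), obs.max(), 50)
        assert np.allclose(tf(x), x, atol=1e-10)

    def test_constant_shift_inverted_on_interior(self, obs):
        shifted = obs + 2.0
        tf = qmap.fit_empirical_qm(obs, shifted)
        x = np.linspace(obs.quantile(0.05), obs.quantile(0.95), 20) + 2.0
        assert np.allclose(tf(x), x - 2.0, atol=1e-9)

    def test_non_overlapping_periods_warn(self, obs):
        other = _normal_series(15, 5, 400, seed=4, start="2030-01-01")
        with pytest.warns(UserWarning, match="overlap"):
            qmap.fit_empirical_qm(obs, other)

    def test_grid_point_oracle_equivalence(self, obs, biased_pair):
        """At the model's own grid quantile values the transfer returns the
        observed quantile at the same level, with no interpolation error."""
        hind, _ = biased_pair
        grid = qmap.quantile_grid()
        tf = qmap.fit_empirical_qm(obs, hind, grid)
        model_q = qmap.empirical_quantiles(hind, grid)
        obs_q = qmap.empirical_quantiles(obs, grid)
        assert np.allclose(tf(model_q), obs_q, atol=1e-12)


class TestLinearQM:
    def test_identity_for_identical_series(self, obs):
        tf = qmap.fit_linear_qm(obs, obs)
        assert tf.params["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert tf.params["slope"] == pytest.approx(1.0, abs=1e-10)

    def test_halving_slope_for_doubled_distribution(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(4000)
        obs = _series(np.sort(base))
        mod = _series(np.sort(2 * base))  # same shape, doubled scale, centered at 0
        tf = qmap.fit_linear_qm(obs, mod)
        assert tf.params["slope"] == pytest.approx(0.5, abs=1e-10)
        assert tf.params["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_model_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            qmap.fit_linear_qm(_series([1, 2, 3]), _series([5, 5, 5]))

    def test_mean_bias_vanishes_on_calibration_data(self, obs, biased_pair):
        hind, _ = biased_pair
        corrected = qmap.apply_transfer(qmap.fit_linear_qm(obs, hind), hind)
        assert hq.compute_metrics(obs, corrected).mbe == pytest.approx(0.0, abs=1e-9)


class TestRobustQM:
    def test_identity_within_bootstrap_noise(self, obs):
        tf = qmap.fit_robust_qm(obs, obs, seed=0)
        dev = np.abs(tf.params["corrected"] - tf.params["model_q"])
        assert dev.max() < 0.1

    def test_exact_linear_qq_relation_recovered(self):
        rng = np.random.default_rng(6)
        base = np.sort(rng.standard_normal(4383))
        obs = _series(base)
        mod = _series(2 * base - 5)  # q-q relation: obs = (mod + 5) / 2
        tf = qmap.fit_robust_qm(obs, mod, seed=1)
        expected = (tf.params["model_q"] + 5) / 2
        assert np.allclose(tf.params["corrected"], expected, atol=1e-8)

    def test_seed_determinism(self, obs, biased_pair):
        hind, _ = biased_pair
        t1 = qmap.fit_robust_qm(obs, hind, seed=9)
        t2 = qmap.fit_robust_qm(obs, hind, seed=9)
        assert (t1.params["corrected"] == t2.params["corrected"]).all()

    def test_k_nearest_validation(self, obs):
        with pytest.raises(ValueError, match="exceeds grid size"):
            qmap.fit_robust_qm(obs, obs, k_nearest=500)
        with pytest.raises(ValueError, match="k_nearest"):
            qmap.fit_robust_qm(obs, obs, k_nearest=1)


class TestQDM:
    def test_reduces_to_empirical_qm_when_distributions_match(self, obs, biased_pair):
        """With the projection distribution equal to the hindcast
        distribution, every delta is zero and QDM equals empirical QM."""
        hind, _ = biased_pair
        grid = qmap.quantile_grid()
        out = qmap.qdm_correct(obs, hind, hind, grid)
        emp = qmap.apply_transfer(qmap.fit_empirical_qm(obs, hind, grid), hind)
        assert np.allclose(out.to_numpy(), emp.to_numpy(), atol=1e-9)

    def test_uniform_shift_preserved(self, obs, biased_pair):
        hind, _ = biased_pair
        shifted = hind + 3.0
        out_shift = qmap.qdm_correct(obs, hind, shifted)
        out_base = qmap.qdm_correct(obs, hind, hind)
        assert out_shift.mean() - out_base.mean() == pytest.approx(3.0, abs=0.05)

    def test_zero_bias_passes_projection_through(self, obs, biased_pair):
        _, proj = biased_pair
        out = qmap.qdm_correct(obs, obs, proj)
        assert np.allclose(out.to_numpy(), proj.to_numpy(), atol=1e-9)

    def test_delta_identity_exact(self, obs, biased_pair):
        """corrected - F_oh^{-1}(tau) equals Delta(t) = x - F_mh^{-1}(tau):
        bitwise on the stored components, and the components agree with an
        independent recomputation."""
        hind, proj = biased_pair
        grid = qmap.quantile_grid()
        parts = qmap.qdm_correct(obs, hind, proj, grid, return_components=True)
        assert (parts["corrected"] == parts["mapped_obs"] + parts["delta"]).all()
        obs_q = qmap.empirical_quantiles(obs, grid)
        mh_q = qmap.empirical_quantiles(hind, grid)
        mp_q = qmap.empirical_quantiles(proj, grid)
        x = proj.to_numpy()
        tau = np.interp(x, mp_q, grid)
        assert (parts["delta"].to_numpy() == x - np.interp(tau, grid, mh_q)).all()
        assert (parts["mapped_obs"].to_numpy() == np.interp(tau, grid, obs_q)).all()

    def test_degenerate_projection_rejected(self, obs):
        flat = _series([5.0] * 400)
        with pytest.raises(ValueError, match="degenerate"):
            qmap.qdm_correct(obs, obs, flat)


class TestApplyTransfer:
    def test_linear_arithmetic(self):
        tf = qmap.TransferFunction("linear", {"intercept": 1.0, "slope": 2.0})
        out = qmap.apply_transfer(tf, _series([3.0]))
        assert out.iloc[0] == 7.0

    def test_dates_and_missing_values_preserved(self, obs, biased_pair):
        hind, _ = biased_pair
        tf = qmap.fit_empirical_qm(obs, hind)
        withnan = hind.copy()
        withnan.iloc[5] = np.nan
        out = qmap.apply_transfer(tf, withnan)
        assert out.index.equals(hind.index)
        assert np.isnan(out.iloc[5]) and not np.isnan(out.iloc[4])

    def test_constant_offset_extrapolation_below_table(self, obs, biased_pair):
        """Below the table minimum the boundary correction (obs min minus
        model min) is applied unchanged."""
        hind, _ = biased_pair
        tf = qmap.fit_empirical_qm(obs, hind)
        model_min = tf.params["model_q"][0]
        offset = tf.params["corrected"][0] - model_min
        probe = model_min - 4.0
        assert tf(probe) == pytest.approx(probe + offset, abs=1e-12)
        model_max = tf.params["model_q"][-1]
        offset_hi = tf.params["corrected"][-1] - model_max
        assert tf(model_max + 4.0) == pytest.approx(model_max + 4.0 + offset_hi, abs=1e-12)

    @pytest.mark.parametrize("method", ["normal", "empirical", "robust", "linear"])
    def test_monotonicity(self, obs, biased_pair, method):
        hind, _ = biased_pair
        tf = qmap.fit_transfer(method, obs, hind, seed=2)
        x = np.linspace(hind.min() - 5, hind.max() + 5, 500)
        assert (np.diff(tf(x)) >= -1e-12).all()


class TestSeasonalFitApply:
    def test_single_season_input_matches_unstratified(self, obs, biased_pair):
        hind, _ = biased_pair
        jja = obs[obs.index.month.isin([6, 7, 8])]
        jja_h = hind[hind.index.month.isin([6, 7, 8])]
        on = qmap.seasonal_fit_apply("empirical", jja, jja_h, jja_h, seasonal=True)
        off = qmap.seasonal_fit_apply("empirical", jja, jja_h, jja_h, seasonal=False)
        assert np.allclose(on.to_numpy(), off.to_numpy())

    def test_season_specific_bias_corrected_locally(self, obs):
        """A +2 degC bias confined to JJA is removed there and nowhere
        else (model = obs + seasonal shift, so no realization noise)."""
        jja = obs.index.month.isin([6, 7, 8])
        skewed = obs.copy()
        skewed[jja] = skewed[jja] + 2.0
        corr = qmap.seasonal_fit_apply("empirical", obs, skewed, skewed, seasonal=True)
        shift_jja = (corr[jja] - skewed[jja]).mean()
        shift_rest = (corr[~jja] - skewed[~jja]).mean()
        assert shift_jja == pytest.approx(-2.0, abs=0.05)
        assert abs(shift_rest) < 0.05

    def test_output_preserves_date_order(self, obs, biased_pair):
        hind, proj = biased_pair
        out = qmap.seasonal_fit_apply("normal", obs, hind, proj)
        assert out.index.equals(proj.index)

    def test_missing_season_rejected(self, obs, biased_pair):
        hind, proj = biased_pair
        summer_only = obs[obs.index.month.isin([6, 7, 8])]
        with pytest.raises(ValueError, match="absent"):
            qmap.seasonal_fit_apply("empirical", summer_only, hind, proj)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-30, 40), min_size=30, max_size=120, unique=True),
       st.lists(st.floats(-30, 40), min_size=30, max_size=120, unique=True))
def test_fitted_transfers_are_monotone_on_random_data(obs_vals, mod_vals):
    """Monotonicity invariant: x1 <= x2 implies g(x1) <= g(x2) for every
    fitted transfer, on arbitrary real-valued calibration data."""
    obs = _series(obs_vals)
    mod = _series(mod_vals)
    x = np.linspace(min(mod_vals) - 2, max(mod_vals) + 2, 60)
    for method in ("normal", "empirical", "linear"):
        tf = qmap.fit_transfer(method, obs, mod)
        assert (np.diff(tf(x)) >= -1e-9).all()
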