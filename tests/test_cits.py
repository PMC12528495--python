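"""SARIMAX fitting, counterfactual simulation, and the Z/CI machinery."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

import modeval as me
from modeval.cits import CitsError, _scale_for
from modeval.synthdata import ar1_series

from conftest import fit_and_test_pair


def _summary(m_hat, s_hat, alpha=0.05, k=10):
    return me.CounterfactualSummary(
        n=100, k=k, B=100, m_hat=m_hat, s_hat=s_hat, M_draws=np.empty(0), alpha=alpha
    )


class TestFitPrePeriod:
    def test_white_noise_search_selects_near_null_model(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 2.0, size=300)
        fit = me.fit_pre_period(y, order="auto", seasonal_period=1)
        p, d, q = fit.spec.order
        assert d == 0
        assert fit.spec.sigma2 == pytest.approx(np.var(y), rel=0.15)

    def test_ar1_coefficient_recovered_over_seeds(self):
        devs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = ar1_series(300, 0.6, 1.0, rng=rng)
            fit = me.fit_pre_period(y, order=(1, 0, 0))
            devs.append(fit.spec.params["ar.L1"] - 0.6)
        assert abs(np.mean(devs)) < 0.05
        assert np.percentile(np.abs(devs), 90) < 0.15

    def test_fixed_order_is_respected(self):
        y = np.random.default_rng(0).normal(size=120)
        fit = me.fit_pre_period(y, order=(1, 0, 0))
        assert fit.spec.order == (1, 0, 0)
        assert fit.spec.seasonal_order == (0, 0, 0, 0)

    def test_nan_series_raises(self):
        y = np.ones(50)
        y[10] = np.nan
        with pytest.raises(CitsError, match="NaN"):
            me.fit_pre_period(y, order=(1, 0, 0))

    def test_constant_exog_columns_are_dropped(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        exog = pd.DataFrame({"flat": np.zeros(200), "step": (np.arange(200) > 100).astype(float)})
        fit = me.fit_pre_period(y, exog=exog, order=(1, 0, 0))
        assert fit.exog_columns == ("step",)


class TestSimulateCounterfactual:
    def test_iid_model_converges_to_mu_and_sigma_over_sqrt_k(self):
        rng = np.random.default_rng(4)
        mu, sigma, k = 3.0, 2.0, 25
        y = rng.normal(mu, sigma, size=2000)
        fit = me.fit_pre_period(y, order=(0, 0, 0))
        cf = me.simulate_counterfactual(fit, k=k, B=4000, seed=9)
        assert cf.m_hat == pytest.approx(mu, abs=4 * sigma / np.sqrt(k * 4000) + 0.05)
        assert cf.s_hat == pytest.approx(sigma / np.sqrt(k), rel=0.1)

    def test_doubling_b_is_stable_within_monte_carlo_error(self):
        y = ar1_series(300, 0.5, 1.0, rng=np.random.default_rng(5))
        fit = me.fit_pre_period(y, order=(1, 0, 0))
        a = me.simulate_counterfactual(fit, k=30, B=500, seed=1)
        b = me.simulate_counterfactual(fit, k=30, B=1000, seed=2)
        assert abs(a.m_hat - b.m_hat) <= 3 * a.s_hat / np.sqrt(500) + 3 * b.s_hat / np.sqrt(1000)

    def test_same_seed_reproduces_draws(self):
        y = ar1_series(200, 0.5, 1.0, rng=np.random.default_rng(6))
        fit = me.fit_pre_period(y, order=(1, 0, 0))
        a = me.simulate_counterfactual(fit, k=10, B=50, seed=77)
        b = me.simulate_counterfactual(fit, k=10, B=50, seed=77)
        np.testing.assert_array_equal(a.M_draws, b.M_draws)

    def test_invalid_horizon_or_b_raises(self):
        y = ar1_series(100, 0.5, 1.0, rng=np.random.default_rng(7))
        fit = me.fit_pre_period(y, order=(1, 0, 0))
        with pytest.raises(CitsError):
            me.simulate_counterfactual(fit, k=0, B=100)
        with pytest.raises(CitsError):
            me.simulate_counterfactual(fit, k=10, B=1)


class TestSingleSeriesZ:
    def test_observed_equal_to_forecast_mean_gives_zero_z(self):
        cf = _summary(m_hat=1.0, s_hat=0.5)
        cf = me.single_series_z(cf, np.full(10, 1.0))
        assert cf.z == pytest.approx(0.0)
        assert cf.ci[0] == pytest.approx(-cf.ci[1])

    def test_observed_at_1_96_sd_touches_ci_boundary(self):
        cf = _summary(m_hat=0.0, s_hat=1.0)
        crit = cf.z_crit
        cf = me.single_series_z(cf, np.full(10, crit))
        assert cf.z == pytest.approx(crit)
        assert cf.ci[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_spread_raises(self):
        cf = _summary(m_hat=0.0, s_hat=0.0)
        with pytest.raises(CitsError, match="s_hat"):
            me.single_series_z(cf, np.zeros(10))

    def test_wrong_horizon_raises(self):
        cf = _summary(m_hat=0.0, s_hat=1.0)
        with pytest.raises(CitsError, match="horizon"):
            me.single_series_z(cf, np.zeros(7))

    def test_null_z_is_approximately_standard_normal(self):
        """Simulation study: over 200 null replicates the Z distribution has
        roughly unit scale and is centred at zero."""
        rng = np.random.default_rng(8)
        zs = []
        for _ in range(200):
            treated, _, _ = fit_and_test_pair(rng, n=360, k=20, B=150)
            zs.append(treated.z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.85 < zs.std() < 1.25


class TestComparativeZ:
    def _completed(self, dev, s_hat, k=10):
        cf = _summary(m_hat=0.0, s_hat=s_hat, k=k)
        return me.single_series_z(cf, np.full(k, dev))

    def test_identical_deviations_give_zero(self):
        a = self._completed(0.7, 0.5)
        b = self._completed(0.7, 0.5)
        comp = me.comparative_z(a, b)
        assert comp.z == pytest.approx(0.0)

    def test_sum_pooling_matches_hand_algebra(self):
        delta, sa, sp = 1.2, 0.4, 0.3
        comp = me.comparative_z(self._completed(delta, sa), self._completed(0.0, sp))
        assert comp.z == pytest.approx(delta / np.sqrt(sa**2 + sp**2))

    def test_swapping_roles_negates_the_numerator(self):
        a = self._completed(1.0, 0.4)
        b = self._completed(0.2, 0.3)
        fwd = me.comparative_z(a, b)
        rev = me.comparative_z(b, a)
        assert fwd.z == pytest.approx(-rev.z)

    def test_as_printed_pooling_raises_on_negative_variance(self):
        a = self._completed(1.0, 0.3)
        b = self._completed(0.0, 0.5)
        with pytest.raises(CitsError, match="non-positive variance"):
            me.comparative_z(a, b, pooling="as_printed")
        # and works when the treated spread dominates
        comp = me.comparative_z(b, a, pooling="as_printed")
        assert comp.z == pytest.approx(-1.0 / np.sqrt(0.5**2 - 0.3**2))

    def test_mismatched_horizons_raise(self):
        a = self._completed(1.0, 0.3, k=10)
        b = self._completed(0.0, 0.3, k=12)
        with pytest.raises(CitsError, match="horizons"):
            me.comparative_z(a, b)


class TestEffectScale:
    @pytest.mark.parametrize(
        "diff,kind,expected",
        [
            (0.0, "content_logit", 1.0),
            (np.log(2.0), "content_logit", 2.0),
            (np.log(1.4), "virality_log", 1.4),
            (-0.07, "quality_mean", -0.07),
            (0.3, "topic_logit(commentary)", np.exp(0.3)),
        ],
    )
    def test_known_transforms(self, diff, kind, expected):
        scale, est = me.effect_scale(diff, kind)
        assert est == pytest.approx(expected)

    def test_round_trip_identity_on_positive_ratios(self):
        for ratio in (0.1, 0.5, 1.0, 1.7, 12.0):
            _, est = me.effect_scale(np.log(ratio), "content_logit")
            assert est == pytest.approx(ratio)

    def test_unknown_kind_raises(self):
        with pytest.raises(CitsError):
            me.effect_scale(0.1, "mystery")

    def test_scale_names(self):
        assert _scale_for("content_logit")[0] == "odds_ratio"
        assert _scale_for("virality_log")[0] == "relative_risk"
        assert _scale_for("quality_mean")[0] == "delta"


def test_rejection_rate_is_monotone_in_effect_size():
    """Power study: rejection at 1.96 never meaningfully decreases as the
    injected post-period odds factor grows through {1.0, 1.25, 1.5, 2.0}."""
    effects = [1.0, 1.25, 1.5, 2.0]
    rates = []
    for effect in effects:
        rng = np.random.default_rng(1234)
        rejects = 0
        n_rep = 25
        for _ in range(n_rep):
            treated, _, _ = fit_and_test_pair(
                rng, n=250, k=25, B=120, shift=np.log(effect)
            )
            rejects += abs(treated.z) > treated.z_crit
        rates.append(rejects / n_rep)
    for lo, hi in zip(rates, rates[1:]):
        assert hi >= lo - 0.08
    assert rates[-1] > rates[0] + 0.3


def test_run_cits_skips_missing_comparator_and_is_antisymmetric():
    rng = np.random.default_rng(9)
    days = pd.date_range("2020-02-07", periods=260, freq="D")
    frames = []
    for comm in ("anti", "pro"):
        frames.append(
            pd.DataFrame(
                {
                    "community": comm,
                    "date": days.date,
                    "measure": "content_logit",
                    "value": ar1_series(len(days), 0.4, 0.3, rng=rng),
                    "n": 100,
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    phases = me.PhaseDesign(
        [
            me.Phase("baseline", date(2020, 2, 7), date(2020, 8, 31)),
            me.Phase("policy", date(2020, 9, 1), date(2020, 10, 23)),
        ]
    )
    fwd = me.run_cits(panel, phases, {"anti": "pro"}, evaluate=["policy"], B=100, seed=3,
                      order=(1, 0, 0))
    rev = me.run_cits(panel, phases, {"pro": "anti"}, evaluate=["policy"], B=100, seed=3,
                      order=(1, 0, 0))
    z_fwd = fwd[fwd["kind"] == "comparative"]["z"].iloc[0]
    z_rev = rev[rev["kind"] == "comparative"]["z"].iloc[0]
    # numerator negates; Monte-Carlo spread in the denominators differs slightly
    assert z_fwd == pytest.approx(-z_rev, abs=0.35)

    skipped = me.run_cits(panel, phases, {"anti": "ghost"}, evaluate=["policy"], B=100, seed=3,
                          order=(1, 0, 0))
    assert len(skipped) == 0

    with pytest.raises(CitsError):
        me.run_cits(panel, phases, {}, evaluate=["policy"])
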