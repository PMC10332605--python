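"""WAIC and PPLC: degenerate closed forms, invariances, ranking."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtri

from occuscale.data import SurveyDataset
from occuscale.multiscale import McmcConfig, ModelSpec, PosteriorDraws, _ModelArrays
from occuscale.selection import ModelScore, pplc, rank_models, waic
import pandas as pd


def _manual_draws(detections, p_draws, a_draws=None, theta_draws=None, psi_draws=None):
    """Build PosteriorDraws by hand from probability draws (intercept models)."""
    site_ids = [f"site{i}" for i in range(len(detections))]
    sample_ids = [[f"S{j}" for j in range(len(s))] for s in detections]
    ds = SurveyDataset(site_ids, sample_ids,
                       [[np.asarray(y, float) for y in s] for s in detections])
    spec = ModelSpec()
    arr = _ModelArrays.build(ds, spec)
    M = len(p_draws)
    n_samples = arr.W_theta.shape[0]
    if a_draws is None:
        a_draws = np.ones((M, n_samples), np.int8)
    to_eta = lambda q: ndtri(np.clip(np.asarray(q, float), 1e-12, 1 - 1e-12))
    cfg = McmcConfig(iterations=max(M + 1, 200), burn_in=1, seed=0)
    return PosteriorDraws(
        beta_psi=to_eta(psi_draws if psi_draws is not None else np.ones(M))[:, None],
        alpha_theta=to_eta(theta_draws if theta_draws is not None else np.ones(M))[:, None],
        delta_p=to_eta(p_draws)[:, None],
        z=np.ones((M, len(detections)), np.int8),
        a=np.asarray(a_draws, np.int8),
        spec=spec, config=cfg, arrays=arr,
    )


class TestWaic:
    def test_point_mass_posterior_closed_form(self):
        """One Bernoulli observation y=1 under a point-mass p=0.5 posterior."""
        draws = _manual_draws([[[1.0]]], p_draws=np.full(300, 0.5))
        crit, p_w = waic(draws, scale="deviance")
        assert p_w == pytest.approx(0.0, abs=1e-20)
        assert crit == pytest.approx(-2 * math.log(0.5), abs=1e-9)
        crit_log, _ = waic(draws)  # log-score scale is half the deviance scale
        assert crit_log == pytest.approx(-math.log(0.5), abs=1e-9)

    def test_conditional_likelihood_uses_binomial_counts(self, rng):
        """With a == 1, WAIC's pointwise unit is Bin(d; K, p) per sample."""
        p_draws = rng.beta(8, 2, 2000)
        draws = _manual_draws([[[1.0, 1.0, 0.0]]], p_draws=p_draws)
        ll = np.log(stats.binom.pmf(2, 3, p_draws))
        lppd = np.log(np.mean(np.exp(ll)))
        p_w = ll.var(ddof=1)
        crit, pvar = waic(draws)
        assert crit == pytest.approx(-(lppd - p_w), rel=1e-10)
        assert pvar == pytest.approx(p_w, rel=1e-10)

    def test_invariant_to_draw_order(self, rng):
        p_draws = rng.beta(5, 3, 1000)
        d1 = _manual_draws([[[1.0, 0.0], [1.0, 1.0]]], p_draws=p_draws)
        d2 = _manual_draws([[[1.0, 0.0], [1.0, 1.0]]], p_draws=p_draws[::-1])
        assert waic(d1) == pytest.approx(waic(d2), rel=1e-12)
        assert pplc(d1) == pytest.approx(pplc(d2), rel=1e-12)

    def test_marginal_partitions_agree_on_totals(self, rng):
        """Sample- and site-partitioned marginal lppd sum to the same criterion
        when every site has one sample (the partitions coincide)."""
        p_draws = rng.beta(5, 3, 800)
        th = rng.beta(4, 4, 800)
        ps = rng.beta(9, 1, 800)
        draws = _manual_draws([[[1.0, 0.0]], [[0.0, 0.0]]], p_draws=p_draws,
                              theta_draws=th, psi_draws=ps)
        w_sample = waic(draws, pointwise="sample", likelihood="marginal")
        w_site = waic(draws, pointwise="site", likelihood="marginal")
        assert w_sample == pytest.approx(w_site, rel=1e-10)

    def test_few_draws_warns(self):
        draws = _manual_draws([[[1.0]]], p_draws=np.full(50, 0.5))
        with pytest.warns(UserWarning, match="draws"):
            waic(draws)


class TestPplc:
    def test_perfect_point_mass_predictions(self):
        draws = _manual_draws([[[1.0, 1.0, 1.0]]], p_draws=np.ones(300))
        assert pplc(draws) == pytest.approx((0.0, 0.0), abs=1e-8)
        assert pplc(draws, level="replicate") == pytest.approx((0.0, 0.0), abs=1e-8)

    def test_beta_posterior_closed_form(self, rng):
        """Replicate-level criterion matches Beta-moment algebra on 2 observations."""
        a_, b_ = 6.0, 3.0
        p_draws = rng.beta(a_, b_, 200_000)
        draws = _manual_draws([[[1.0, 0.0]]], p_draws=p_draws)
        m = a_ / (a_ + b_)  # E p
        ep2 = m * (a_ + 1) / (a_ + b_ + 1)  # E p^2
        v = (m - ep2) + (ep2 - m**2)  # E[p(1-p)] + Var p
        expected_G = (1 - m) ** 2 + m**2
        crit, P = pplc(draws, level="replicate")
        assert P == pytest.approx(2 * v, rel=0.01)
        assert crit == pytest.approx(expected_G + 2 * v, rel=0.01)

    def test_sample_count_version_closed_form(self, rng):
        p_draws = rng.beta(6, 3, 100_000)
        draws = _manual_draws([[[1.0, 1.0, 0.0]]], p_draws=p_draws)
        mean_d = 3 * p_draws.mean()
        var_d = np.mean(3 * p_draws * (1 - p_draws)) + np.var(3 * p_draws)
        crit, P = pplc(draws)
        assert crit == pytest.approx((2 - mean_d) ** 2 + var_d, rel=1e-6)
        assert P == pytest.approx(var_d, rel=1e-6)


class TestRanking:
    def _score(self, name, waic_val, n_coef):
        return ModelScore(name=name, waic=waic_val, waic_pvar=1.0, pplc=waic_val,
                          pplc_pvar=0.5, n_coefficients=n_coef)

    def test_orders_by_waic(self):
        table = rank_models([self._score("b", 32.0, 3), self._score("a", 30.0, 4)])
        assert list(table["model"]) == ["a", "b"]

    def test_tie_break_prefers_smaller_model(self):
        table = rank_models([self._score("big", 30.0, 6), self._score("small", 30.0, 3)])
        assert list(table["model"]) == ["small", "big"]

    def test_permutation_invariance(self):
        scores = [self._score(n, w, 3) for n, w in [("a", 31.0), ("b", 30.0), ("c", 33.0)]]
        t1 = rank_models(scores)
        t2 = rank_models(scores[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_requires_two_models(self):
        with pytest.raises(ValueError):
            rank_models([self._score("only", 30.0, 3)])


def test_noise_covariate_does_not_shrink_penalty_on_average(rng):
    """Adding a pure-noise theta covariate inflates pW on average (20 fits)."""
    from occuscale.multiscale import sample_posterior
    from occuscale.simulate import SimulationParams, simulate_multiscale

    diffs = []
    for k in range(20):
        params = SimulationParams(
            n_sites=15, samples_per_site=4, replicates_per_sample=3,
            beta_psi=(1.3,), alpha_theta=(0.4,), delta_p=(1.0,),
            seed=1000 + k, covariates={"noise": ("normal", 0.0, 1.0)},
        )
        ds, _ = simulate_multiscale(params)
        cfg = McmcConfig(iterations=1500, burn_in=300, seed=2000 + k)
        null = sample_posterior(ds, ModelSpec(), cfg)
        noisy = sample_posterior(ds, ModelSpec(theta=("noise",)), cfg)
        diffs.append(waic(noisy)[1] - waic(null)[1])
    assert np.mean(diffs) > 0
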