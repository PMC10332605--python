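"""Three-level model: likelihood oracle, sampler invariants, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from occuscale.classic import ClassicHistories, fit_classic
from occuscale.data import DegenerateScaleError, SurveyDataset
from occuscale.multiscale import (
    McmcConfig,
    ModelSpec,
    covariate_effect_flag,
    multiscale_loglik,
    sample_posterior,
    summarize,
)


def exhaustive_loglik(psi_site, theta_site, p, detections):
    """Sum the likelihood over every latent (z, a) configuration.

    ``detections``: nested per-site lists of replicate arrays (NaN = missing).
    Site-level theta/p (constant within site) keeps the enumeration simple.
    """
    n_sites = len(detections)
    n_samples = [len(s) for s in detections]
    total_ll = 0.0
    for i in range(n_sites):
        site_lik = 0.0
        for z in (0, 1):
            pz = psi_site[i] if z else 1 - psi_site[i]
            a_states = itertools.product(*[(0, 1)] * n_samples[i]) if z else [(0,) * n_samples[i]]
            z_lik = 0.0
            for a_vec in a_states:
                lik = 1.0
                for j, a in enumerate(a_vec):
                    if z:
                        lik *= theta_site[i] if a else 1 - theta_site[i]
                    for y in detections[i][j]:
                        if np.isnan(y):
                            continue
                        if a:
                            lik *= p[i] if y == 1 else 1 - p[i]
                        elif y == 1:
                            lik = 0.0
                z_lik += lik
            site_lik += pz * z_lik
        total_ll += math.log(site_lik)
    return total_ll


def _dataset(detections, density=None):
    site_ids = [f"site{i}" for i in range(len(detections))]
    sample_ids = [[f"S{j}" for j in range(len(s))] for s in detections]
    cov = None
    if density is not None:
        cov = pd.DataFrame({"density": density}, index=site_ids)
    return SurveyDataset(site_ids, sample_ids,
                         [[np.asarray(y, float) for y in s] for s in detections],
                         site_covariates=cov if cov is not None else pd.DataFrame())


class TestMarginalLoglik:
    def test_closed_form_single_observation(self):
        ds = _dataset([[[1.0]]])
        ll = multiscale_loglik([0.0], [0.0], [0.0], ds, ModelSpec(), link="probit")
        assert ll == pytest.approx(math.log(0.125), abs=1e-12)  # psi=theta=p=0.5

    def test_matches_exhaustive_enumeration(self, rng):
        """Random ragged datasets with <= 16 latent binaries, 1e-10 agreement."""
        for trial in range(25):
            n_sites = int(rng.integers(2, 4))
            shapes = [int(rng.integers(1, 4)) for _ in range(n_sites)]
            detections = []
            for s in shapes:
                site = []
                for _ in range(s):
                    y = rng.integers(0, 2, size=int(rng.integers(1, 4))).astype(float)
                    if rng.random() < 0.2:
                        y[rng.integers(0, y.size)] = np.nan
                    site.append(y)
                detections.append(site)
            assert n_sites + sum(shapes) <= 16
            density = rng.normal(0, 1, n_sites)
            ds = _dataset(detections, density)
            b0 = rng.normal(0, 1.5)
            a0, a1 = rng.normal(0, 1.0, 2)
            d0 = rng.normal(0, 1.0)
            spec = ModelSpec(theta=("density",))
            ll = multiscale_loglik([b0], [a0, a1], [d0], ds, spec)
            psi = ndtr(np.full(n_sites, b0))
            theta = ndtr(a0 + a1 * density)
            p = ndtr(np.full(n_sites, d0))
            assert ll == pytest.approx(
                exhaustive_loglik(psi, theta, p, detections), abs=1e-10
            )

    def test_all_detected_limit(self):
        ds = _dataset([[[1.0, 1.0], [1.0, 1.0]], [[1.0, 1.0]]])
        ll = multiscale_loglik([8.0], [8.0], [8.0], ds, ModelSpec())
        assert -1e-9 < ll <= 0

    def test_shape_error_on_wrong_coefficient_length(self):
        ds = _dataset([[[1.0]]])
        with pytest.raises(ValueError, match="length"):
            multiscale_loglik([0.0, 1.0], [0.0], [0.0], ds, ModelSpec())


@pytest.fixture(scope="module")
def short_field_draws(request):
    from occuscale.data import standardize_covariates
    from occuscale.datasets import field_control_dataset

    ds = standardize_covariates(field_control_dataset(), ["density"])
    cfg = McmcConfig(iterations=4000, burn_in=1000, seed=7)
    return ds, sample_posterior(ds, ModelSpec(theta=("density",)), cfg)


class TestSampler:
    def test_seeded_determinism(self, field_dataset):
        cfg = McmcConfig(iterations=600, burn_in=200, seed=42)
        spec = ModelSpec(theta=("density",))
        d1 = sample_posterior(field_dataset, spec, cfg)
        d2 = sample_posterior(field_dataset, spec, cfg)
        np.testing.assert_array_equal(d1.beta_psi, d2.beta_psi)
        np.testing.assert_array_equal(d1.delta_p, d2.delta_p)
        np.testing.assert_array_equal(d1.a, d2.a)

    def test_latent_state_consistency(self, short_field_draws):
        ds, draws = short_field_draws
        arr = draws.arrays
        # a = 0 wherever z = 0, for every retained draw
        z_by_sample = draws.z[:, arr.sample_site]
        assert not np.any((draws.a == 1) & (z_by_sample == 0))
        # sites and samples with observed detections are always occupied
        assert np.all(draws.z[:, arr.det_site] == 1)
        assert np.all(draws.a[:, arr.det_sample] == 1)

    def test_monotone_theta_in_density_per_draw(self, short_field_draws):
        ds, draws = short_field_draws
        theta = draws.theta_draws()
        dens = ds.sample_covariate_values("density")
        hi, lo = int(np.argmax(dens)), int(np.argmin(dens))
        pos_slope = draws.alpha_theta[:, 1] > 0
        assert np.all(theta[pos_slope, hi] >= theta[pos_slope, lo])

    def test_all_positive_dataset_forces_high_probabilities(self):
        ds = _dataset([[[1.0, 1.0, 1.0]] * 3] * 6)
        draws = sample_posterior(ds, ModelSpec(),
                                 McmcConfig(iterations=3000, burn_in=500, seed=1))
        assert np.median(draws.psi_draws()) > 0.9
        assert np.median(draws.theta_draws()) > 0.9
        assert np.median(draws.p_draws()) > 0.9

    def test_flat_prior_posterior_approaches_two_level_mle(self, rng):
        """One sample per site collapses the model: psi*theta and p should
        match the classic two-level MLE once the prior is nearly flat."""
        z = rng.random(150) < 0.7
        d = rng.binomial(4, 0.75 * z)
        ds = _dataset([[np.concatenate([np.ones(di), np.zeros(4 - di)])] for di in d])
        draws = sample_posterior(
            ds, ModelSpec(),
            McmcConfig(iterations=6000, burn_in=1000, seed=3, prior_sd=10.0),
        )
        occ = np.median(draws.psi_draws()[:, 0] * draws.theta_draws()[:, 0])
        p_med = np.median(draws.p_draws())
        mle = fit_classic(ClassicHistories(d, np.full(150, 4)))
        assert occ == pytest.approx(mle.psi_hat, abs=0.02)
        assert p_med == pytest.approx(mle.p_hat, abs=0.02)

    def test_degenerate_covariate_is_hard_error(self):
        ds = _dataset([[[1.0]], [[0.0]]], density=[2.0, 2.0])
        with pytest.raises(DegenerateScaleError):
            sample_posterior(ds, ModelSpec(theta=("density",)),
                             McmcConfig(iterations=200, burn_in=50, seed=0))


class TestConfigAndSummaries:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.raises(ValueError):
            McmcConfig(link="cauchit")

    def test_draw_count(self):
        cfg = McmcConfig(iterations=10_000, burn_in=2_000, thin=4)
        assert cfg.n_draws == 2000

    def test_summarize_constant_draws(self):
        s = summarize(np.full(500, 1.3), names=["c"])
        row = s.loc["c"]
        assert row["median"] == 1.3
        assert row["cri_lower"] == row["cri_upper"] == 1.3

    def test_summarize_transform_commutes_for_median(self, rng):
        draws = rng.normal(1.0, 0.7, 4001)  # odd length: median is an order stat
        s = summarize(draws, names=["b"], transform=ndtr)
        assert s.loc["b", "median"] == pytest.approx(ndtr(np.median(draws)), abs=1e-9)

    def test_summarize_mcse_matches_iid_theory(self, rng):
        draws = rng.normal(0, 1, 10_000)
        s = summarize(draws, names=["x"])
        assert s.loc["x", "mcse"] == pytest.approx(1 / np.sqrt(10_000), rel=0.35)

    def test_summarize_guards(self):
        with pytest.raises(ValueError):
            summarize(np.empty(0))
        with pytest.warns(UserWarning, match="100"):
            summarize(np.arange(50.0))

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.306, 1.896, True), (-0.2, 0.4, False), (0.0, 0.5, False)],
    )
    def test_covariate_effect_flag(self, lo, hi, expected):
        row = pd.Series({"cri_lower": lo, "cri_upper": hi})
        assert covariate_effect_flag(row) is expected

    def test_spec_formula_parsing(self):
        spec = ModelSpec.from_formulas("~1", "~density + temp", "~sc")
        assert spec.psi == () and spec.theta == ("density", "temp") and spec.p == ("sc",)
        assert spec.n_coefficients == 6
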