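"""Predictive model-selection criteria for multiscale occupancy fits.

Two criteria, both smaller-is-better, both computed from the retained MCMC
draws (coefficients plus sampled latent states):

* **WAIC** (widely applicable information criterion).  The default follows
  the convention of the multiscale-occupancy literature: the pointwise
  observation is the *water sample's* positive-replicate count ``d_j`` with
  a binomial likelihood conditional on the sampled capture indicator
  ``a_j`` (``Bin(d_j; K_j, a_j p)``; an empty sample under ``a_j = 0``
  contributes likelihood one), and the criterion is reported on the
  log-score scale ``WAIC = -(lppd - pW)`` with
  ``pW = sum_j var_m log p(d_j | .)``.  Alternatives are available: the
  fully latent-state-marginalized likelihood (``likelihood='marginal'``,
  partitioned by sample or site with each site's occupancy factor
  apportioned across its samples) and the conventional deviance scale
  (``scale='deviance'``, i.e. ``-2(lppd - pW)``).

* **PPLC** (posterior-predictive loss criterion) under squared-error loss
  in the infinite-weight limit: ``PPLC = G + P`` where, per water sample,
  the predictive replicate is ``d~_j ~ Bin(K_j, a_j p)`` conditional on the
  sampled latent state, ``G = sum_j (d_j - E d~_j)^2`` and
  ``P = sum_j Var d~_j``.  A replicate-level variant (per-qPCR Bernoulli
  observations) is available via ``level='replicate'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .multiscale import ModelSpec, PosteriorDraws

__all__ = ["ModelScore", "waic", "pplc", "rank_models", "score_model"]


@dataclass(frozen=True)
class ModelScore:
    name: str
    waic: float
    waic_pvar: float
    pplc: float
    pplc_pvar: float
    n_coefficients: int
    spec: ModelSpec | None = None


def _sample_counts(draws: PosteriorDraws):
    """Per-sample positive counts d, trials K, and per-sample p draws."""
    arr = draws.arrays
    obs = ~arr.miss
    rs = arr.rep_sample
    n_samples = arr.W_theta.shape[0]
    d = np.bincount(rs[obs], weights=arr.y[obs], minlength=n_samples)
    K = np.bincount(rs[obs], minlength=n_samples).astype(float)
    return d, K, obs, rs


def _conditional_sample_loglik(draws: PosteriorDraws) -> np.ndarray:
    """(M, n_samples) log Bin(d_j; K_j, a_j p) conditional on sampled a."""
    arr = draws.arrays
    d, K, obs, rs = _sample_counts(draws)
    p = draws.p_draws()
    # p is constant within a sample by construction (replicate design rows
    # are broadcast from sample/site covariates); take each sample's first
    first_rep = np.array([np.flatnonzero(rs == s)[0] for s in range(d.size)])
    ps = p[:, first_rep]
    lC = gammaln(K + 1) - gammaln(d + 1) - gammaln(K - d + 1)
    with np.errstate(divide="ignore"):
        ll_pos = lC + d * np.log(ps) + (K - d) * np.log1p(-ps)
    # a = 0 forces an empty sample: likelihood 1 when d = 0, impossible otherwise
    ll = np.where(draws.a == 1, ll_pos, np.where(d == 0, 0.0, -np.inf))
    return ll


def _marginal_pointwise_loglik(draws: PosteriorDraws, pointwise: str) -> np.ndarray:
    """(M, n_points) latent-marginalized pointwise log-likelihoods."""
    arr = draws.arrays
    theta = draws.theta_draws()
    p = draws.p_draws()
    psi = draws.psi_draws()
    M = theta.shape[0]
    obs = ~arr.miss
    rs = arr.rep_sample
    n_samples = theta.shape[1]
    n_sites = psi.shape[1]

    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    ll_rep = np.where(arr.y == 1, logp, log1mp)
    ll_obs = np.zeros((M, n_samples))
    logq0 = np.zeros((M, n_samples))
    for s in range(n_samples):
        cols = np.flatnonzero((rs == s) & obs)
        if cols.size:
            ll_obs[:, s] = ll_rep[:, cols].sum(axis=1)
            logq0[:, s] = log1mp[:, cols].sum(axis=1)

    log_Lj = np.where(
        arr.det_sample,
        np.log(np.clip(theta, 1e-300, None)) + ll_obs,
        np.log(np.clip(theta * np.exp(logq0) + (1 - theta), 1e-300, None)),
    )
    J = np.bincount(arr.sample_site, minlength=n_sites)
    log_psi = np.log(np.clip(psi, 1e-300, None))

    if pointwise == "site":
        pts = np.empty((M, n_sites))
    else:
        pts = np.empty((M, n_samples))
    for i in range(n_sites):
        cols = np.flatnonzero(arr.sample_site == i)
        site_sum = log_Lj[:, cols].sum(axis=1)
        if arr.det_site[i]:
            site_pts = log_Lj[:, cols] + (log_psi[:, i] / J[i])[:, None]
            site_total = log_psi[:, i] + site_sum
        else:
            site_total = np.log(np.clip(
                psi[:, i] * np.exp(site_sum) + (1 - psi[:, i]), 1e-300, None))
            site_pts = np.repeat((site_total / J[i])[:, None], J[i], axis=1)
        if pointwise == "site":
            pts[:, i] = site_total
        else:
            pts[:, cols] = site_pts
    return pts


def waic(draws: PosteriorDraws, pointwise: str = "sample",
         likelihood: str = "conditional", scale: str = "log") -> tuple[float, float]:
    """Return ``(criterion, pW)``.

    Defaults (``pointwise='sample'``, ``likelihood='conditional'``,
    ``scale='log'``) reproduce the criterion convention used for published
    multiscale eDNA occupancy analyses; see the module docstring for the
    alternatives.
    """
    if draws.n_draws < 100:
        warnings.warn("fewer than 100 draws: WAIC variance term is unstable",
                      stacklevel=2)
    if likelihood == "conditional":
        if pointwise != "sample":
            raise ValueError("conditional likelihood is defined per sample")
        ll = _conditional_sample_loglik(draws)
    elif likelihood == "marginal":
        ll = _marginal_pointwise_loglik(draws, pointwise)
    else:
        raise ValueError("likelihood must be 'conditional' or 'marginal'")

    mx = ll.max(axis=0)
    lppd = float(np.sum(mx + np.log(np.exp(ll - mx).mean(axis=0))))
    finite = np.where(np.isfinite(ll), ll, np.nan)  # -inf rows never retained
    p_w = float(np.nansum(np.nanvar(finite, axis=0, ddof=1)))
    factor = 2.0 if scale == "deviance" else 1.0
    return factor * (p_w - lppd), p_w


def pplc(draws: PosteriorDraws, level: str = "sample") -> tuple[float, float]:
    """Return ``(PPLC, P)``: squared-error criterion ``G + P`` and penalty ``P``."""
    arr = draws.arrays
    d, K, obs, rs = _sample_counts(draws)
    p = draws.p_draws()
    if level == "sample":
        first_rep = np.array([np.flatnonzero(rs == s)[0] for s in range(d.size)])
        q = draws.a * p[:, first_rep]  # per-draw success prob of this sample's reps
        mean_d = (K * q).mean(axis=0)
        var_d = (K * q * (1 - q)).mean(axis=0) + (K * q).var(axis=0)
        G = float(np.sum((d - mean_d) ** 2))
        P = float(np.sum(var_d))
    elif level == "replicate":
        q = draws.a[:, rs] * p
        q = q[:, obs]
        y = arr.y[obs]
        m = q.mean(axis=0)
        v = (q * (1 - q)).mean(axis=0) + q.var(axis=0)
        G = float(np.sum((y - m) ** 2))
        P = float(np.sum(v))
    else:
        raise ValueError("level must be 'sample' or 'replicate'")
    return G + P, P


def score_model(draws: PosteriorDraws, name: str | None = None) -> ModelScore:
    w, wp = waic(draws)
    c, cp = pplc(draws)
    return ModelScore(
        name=name or draws.spec.name(),
        waic=w, waic_pvar=wp, pplc=c, pplc_pvar=cp,
        n_coefficients=draws.spec.n_coefficients, spec=draws.spec,
    )


def rank_models(scores: list[ModelScore]) -> pd.DataFrame:
    """Ascending-WAIC table; ties broken by fewer coefficients, then name."""
    if len(scores) < 2:
        raise ValueError("need at least two models to rank")
    rows = sorted(scores, key=lambda s: (s.waic, s.n_coefficients, s.name))
    df = pd.DataFrame(
        [
            {
                "model": s.name,
                "waic": s.waic,
                "waic_pvar": s.waic_pvar,
                "pplc": s.pplc,
                "pplc_pvar": s.pplc_pvar,
                "n_coefficients": s.n_coefficients,
            }
            for s in rows
        ]
    )
    df["pplc_rank"] = df["pplc"].rank(method="min").astype(int)
    return df
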