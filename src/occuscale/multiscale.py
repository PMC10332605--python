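"""Three-level Bayesian multiscale occupancy model for nested eDNA data.

The hierarchy mirrors the nested survey design:

    z_i  ~ Bernoulli(psi_i)            eDNA present at site i
    a_ij | z_i ~ Bernoulli(z_i theta_ij)   eDNA captured in water sample j
    y_ijk | a_ij ~ Bernoulli(a_ij p_ijk)   eDNA amplified in qPCR replicate k

with probabilities modelled through a link function (probit by default,
logit optional) as linear functions of standardized covariates; each level
has an implicit intercept.  Priors are independent normal(0, prior_sd) on
all coefficients.

Inference is Metropolis-within-Gibbs: the latent indicators z and a are
drawn from their exact Bernoulli full conditionals, and each coefficient
block takes an adaptive random-walk Metropolis step (adaptation runs only
during burn-in and is frozen afterwards, so the retained chain is a valid
fixed-kernel sampler).  Everything is driven by one integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, log_ndtr, ndtr, ndtri

from .data import DegenerateScaleError, SurveyDataset

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "LatentState",
    "PosteriorDraws",
    "multiscale_loglik",
    "sample_posterior",
    "summarize",
    "covariate_effect_flag",
]

_ADAPT_INTERVAL = 50
_TARGET_ACCEPT = 0.37  # middle of the 0.3-0.45 band for low-dim random walks


# ---------------------------------------------------------------------------
# links
def _inv_link(link: str) -> Callable[[np.ndarray], np.ndarray]:
    return ndtr if link == "probit" else expit


def _log_link_cdf(link: str) -> Callable[[np.ndarray], np.ndarray]:
    # log F(x); log(1-F(x)) is the same function at -x for both links
    return log_ndtr if link == "probit" else log_expit


def link_quantile(link: str, prob: float) -> float:
    """Inverse of the link's CDF (useful for setting simulation intercepts)."""
    return float(ndtri(prob)) if link == "probit" else float(np.log(prob / (1 - prob)))


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    """Covariate names per level; every level has an implicit intercept.

    The formula mini-language accepted by :meth:`from_formulas` is
    ``"~1"`` (intercept only) or ``"~a + b"``.
    """

    psi: tuple[str, ...] = ()
    theta: tuple[str, ...] = ()
    p: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi", tuple(self.psi))
        object.__setattr__(self, "theta", tuple(self.theta))
        object.__setattr__(self, "p", tuple(self.p))

    @classmethod
    def from_formulas(cls, psi: str = "~1", theta: str = "~1", p: str = "~1") -> "ModelSpec":
        return cls(_parse_formula(psi), _parse_formula(theta), _parse_formula(p))

    @property
    def n_coefficients(self) -> int:
        return 3 + len(self.psi) + len(self.theta) + len(self.p)

    def name(self) -> str:
        def block(sym: str, names: tuple[str, ...]) -> str:
            return f"{sym}({' + '.join(names) if names else '.'})"

        return block("psi", self.psi) + block("theta", self.theta) + block("p", self.p)


def _parse_formula(formula: str) -> tuple[str, ...]:
    body = formula.strip().lstrip("~").strip()
    if body in ("", "1"):
        return ()
    return tuple(t.strip() for t in body.split("+") if t.strip() not in ("", "1"))


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    proposal_scale: float = 0.3
    prior_sd: float = 1.0
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_scale <= 0 or self.prior_sd <= 0:
            raise ValueError("proposal_scale and prior_sd must be positive")
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class LatentState:
    """Binary occupancy indicators: z per site, a per sample (flat order)."""

    z: np.ndarray
    a: np.ndarray


# ---------------------------------------------------------------------------
# design matrices
def _design(dataset: SurveyDataset, names: Sequence[str], level: str) -> np.ndarray:
    if level == "site":
        n = dataset.n_sites
        cols = [dataset.site_covariate_values(nm) for nm in names]
    elif level == "sample":
        n = dataset.n_samples
        cols = [dataset.sample_covariate_values(nm) for nm in names]
    else:  # replicate level: site/sample covariates broadcast to replicates
        flat = dataset.flatten()
        n = flat["y"].size
        cols = [dataset.sample_covariate_values(nm)[flat["rep_sample"]] for nm in names]
    X = np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in cols])
    for nm, col in zip(names, X.T[1:]):
        if np.ptp(col) == 0:
            raise DegenerateScaleError(f"covariate {nm!r} is constant in this dataset")
    return X


@dataclass
class _ModelArrays:
    """Flattened dataset plus design matrices, shared by likelihood and sampler."""

    y: np.ndarray
    miss: np.ndarray
    rep_sample: np.ndarray
    sample_site: np.ndarray
    det_sample: np.ndarray  # bool, any observed detection in sample
    det_site: np.ndarray
    X_psi: np.ndarray
    W_theta: np.ndarray
    V_p: np.ndarray

    @classmethod
    def build(cls, dataset: SurveyDataset, spec: ModelSpec) -> "_ModelArrays":
        flat = dataset.flatten()
        y = flat["y"]
        miss = np.isnan(y)
        rep_sample = flat["rep_sample"]
        sample_site = flat["sample_site"]
        n_samples = sample_site.size
        det_sample = np.zeros(n_samples, bool)
        np.logical_or.at(det_sample, rep_sample[~miss], y[~miss] == 1)
        det_site = np.zeros(dataset.n_sites, bool)
        np.logical_or.at(det_site, sample_site, det_sample)
        return cls(
            y=np.where(miss, 0.0, y),
            miss=miss,
            rep_sample=rep_sample,
            sample_site=sample_site,
            det_sample=det_sample,
            det_site=det_site,
            X_psi=_design(dataset, spec.psi, "site"),
            W_theta=_design(dataset, spec.theta, "sample"),
            V_p=_design(dataset, spec.p, "replicate"),
        )


def _sample_loglik_terms(arr: _ModelArrays, theta, p, log1m_p, link: str):
    """Per-sample log L_j marginal over a_j, given z at the sample's site = 1.

    L_j = theta_j * prod_k Bern(y_jk; p_jk) + (1 - theta_j) * [all y_j. = 0]
    Missing replicates are skipped.  Returns per-sample log-likelihoods.
    """
    n_samples = arr.W_theta.shape[0]
    obs = ~arr.miss
    # sum_k log Bern(y; p) and sum_k log(1-p) per sample
    ll_rep = np.where(arr.y == 1, np.log(np.clip(p, 1e-300, None)), log1m_p)
    ll_obs = np.zeros(n_samples)
    np.add.at(ll_obs, arr.rep_sample[obs], ll_rep[obs])
    logq0 = np.zeros(n_samples)
    np.add.at(logq0, arr.rep_sample[obs], log1m_p[obs])

    out = np.empty(n_samples)
    pos = arr.det_sample
    out[pos] = np.log(np.clip(theta[pos], 1e-300, None)) + ll_obs[pos]
    q = theta[~pos] * np.exp(logq0[~pos]) + (1 - theta[~pos])
    out[~pos] = np.log(np.clip(q, 1e-300, None))
    return out, logq0


def multiscale_loglik(beta_psi, alpha_theta, delta_p, dataset: SurveyDataset,
                      spec: ModelSpec, link: str = "probit",
                      _arrays: _ModelArrays | None = None) -> float:
    """Marginal log-likelihood with both latent levels summed out.

    Per site: log[ psi_i prod_j L_j + (1 - psi_i) [no detection at site i] ].
    """
    arr = _arrays if _arrays is not None else _ModelArrays.build(dataset, spec)
    beta_psi = np.atleast_1d(np.asarray(beta_psi, float))
    alpha_theta = np.atleast_1d(np.asarray(alpha_theta, float))
    delta_p = np.atleast_1d(np.asarray(delta_p, float))
    for vec, X, nm in ((beta_psi, arr.X_psi, "beta_psi"),
                       (alpha_theta, arr.W_theta, "alpha_theta"),
                       (delta_p, arr.V_p, "delta_p")):
        if vec.shape != (X.shape[1],):
            raise ValueError(f"{nm} must have length {X.shape[1]}, got {vec.shape}")

    inv = _inv_link(link)
    logF = _log_link_cdf(link)
    psi = inv(arr.X_psi @ beta_psi)
    theta = inv(arr.W_theta @ alpha_theta)
    eta_p = arr.V_p @ delta_p
    p = inv(eta_p)
    log1m_p = logF(-eta_p)

    log_Lj, _ = _sample_loglik_terms(arr, theta, p, log1m_p, link)
    n_sites = arr.X_psi.shape[0]
    site_sum = np.zeros(n_sites)
    np.add.at(site_sum, arr.sample_site, log_Lj)

    ll = 0.0
    for i in range(n_sites):
        if arr.det_site[i]:
            ll += np.log(np.clip(psi[i], 1e-300, None)) + site_sum[i]
        else:
            ll += np.log(np.clip(psi[i] * np.exp(site_sum[i]) + (1 - psi[i]), 1e-300, None))
    return float(ll)


# ---------------------------------------------------------------------------
@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus enough context to derive probabilities."""

    beta_psi: np.ndarray  # (M, k_psi)
    alpha_theta: np.ndarray
    delta_p: np.ndarray
    z: np.ndarray  # (M, n_sites) int8
    a: np.ndarray  # (M, n_samples) int8
    spec: ModelSpec
    config: McmcConfig
    arrays: _ModelArrays
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta_psi.shape[0]

    @property
    def link(self) -> str:
        return self.config.link

    def psi_draws(self) -> np.ndarray:
        """(M, n_sites) site occurrence probabilities."""
        return _inv_link(self.link)(self.beta_psi @ self.arrays.X_psi.T)

    def theta_draws(self) -> np.ndarray:
        """(M, n_samples) conditional sample-capture probabilities."""
        return _inv_link(self.link)(self.alpha_theta @ self.arrays.W_theta.T)

    def p_draws(self) -> np.ndarray:
        """(M, n_replicates) conditional replicate-detection probabilities."""
        return _inv_link(self.link)(self.delta_p @ self.arrays.V_p.T)

    def site_theta_draws(self, site_index: int) -> np.ndarray:
        """theta draws for the first sample of one site (site-level covariates)."""
        j = int(np.flatnonzero(self.arrays.sample_site == site_index)[0])
        return self.theta_draws()[:, j]

    def coefficients_frame(self) -> pd.DataFrame:
        cols = {}
        for block, names, draws in (
            ("beta_psi", self.spec.psi, self.beta_psi),
            ("alpha_theta", self.spec.theta, self.alpha_theta),
            ("delta_p", self.spec.p, self.delta_p),
        ):
            labels = ("intercept",) + tuple(names)
            for k, lab in enumerate(labels):
                cols[f"{block}[{lab}]"] = draws[:, k]
        return pd.DataFrame(cols)


def _block_loglik_psi(beta, arr, z, link):
    eta = arr.X_psi @ beta
    logF = _log_link_cdf(link)
    signed = np.where(z == 1, eta, -eta)  # log F(eta) or log(1-F(eta)) = log F(-eta)
    return float(logF(signed).sum())


def _block_loglik_theta(alpha, arr, z, a, link):
    eta = arr.W_theta @ alpha
    logF = _log_link_cdf(link)
    active = z[arr.sample_site] == 1
    signed = np.where(a == 1, eta, -eta)[active]
    return float(logF(signed).sum())


def _block_loglik_p(delta, arr, a, link):
    eta = arr.V_p @ delta
    logF = _log_link_cdf(link)
    active = (a[arr.rep_sample] == 1) & ~arr.miss
    signed = np.where(arr.y == 1, eta, -eta)[active]
    return float(logF(signed).sum())


def sample_posterior(dataset: SurveyDataset, spec: ModelSpec,
                     config: McmcConfig) -> PosteriorDraws:
    """Draw from the posterior of the multiscale model.

    One chain; latent z and a are refreshed from exact full conditionals at
    every iteration, then each coefficient block takes a random-walk
    Metropolis step under its normal(0, prior_sd) prior.  Proposal scales
    adapt toward ~0.37 acceptance during burn-in only.
    """
    arr = _ModelArrays.build(dataset, spec)
    rng = np.random.default_rng(config.seed)
    inv = _inv_link(config.link)

    if not arr.det_site.any():
        warnings.warn("no detections anywhere: posterior is prior-dominated", stacklevel=2)

    n_sites, n_samples = arr.X_psi.shape[0], arr.W_theta.shape[0]
    beta = np.zeros(arr.X_psi.shape[1])
    alpha = np.zeros(arr.W_theta.shape[1])
    delta = np.zeros(arr.V_p.shape[1])
    z = arr.det_site.astype(np.int8).copy()
    a = arr.det_sample.astype(np.int8).copy()

    scales = {k: config.proposal_scale for k in ("psi", "theta", "p")}
    acc = {k: 0 for k in scales}
    acc_window = {k: 0 for k in scales}
    prior_var = config.prior_sd**2

    M = config.n_draws
    out_beta = np.empty((M, beta.size))
    out_alpha = np.empty((M, alpha.size))
    out_delta = np.empty((M, delta.size))
    out_z = np.empty((M, n_sites), np.int8)
    out_a = np.empty((M, n_samples), np.int8)

    cur_ll = {
        "psi": _block_loglik_psi(beta, arr, z, config.link),
        "theta": _block_loglik_theta(alpha, arr, z, a, config.link),
        "p": _block_loglik_p(delta, arr, a, config.link),
    }
    logF = _log_link_cdf(config.link)
    obs_mask = ~arr.miss
    obs_idx = arr.rep_sample[obs_mask]

    m = 0
    for it in range(config.iterations):
        # --- coefficient blocks (random-walk Metropolis) -----------------
        for name in ("psi", "theta", "p"):
            vec = {"psi": beta, "theta": alpha, "p": delta}[name]
            prop = vec + scales[name] * rng.standard_normal(vec.size)
            if name == "psi":
                ll_new = _block_loglik_psi(prop, arr, z, config.link)
            elif name == "theta":
                ll_new = _block_loglik_theta(prop, arr, z, a, config.link)
            else:
                ll_new = _block_loglik_p(prop, arr, a, config.link)
            log_r = (ll_new - cur_ll[name]
                     + (vec @ vec - prop @ prop) / (2 * prior_var))
            if np.log(rng.random()) < log_r:
                vec[:] = prop
                cur_ll[name] = ll_new
                acc[name] += 1
                acc_window[name] += 1
        if it < config.burn_in and (it + 1) % _ADAPT_INTERVAL == 0:
            for name in scales:
                rate = acc_window[name] / _ADAPT_INTERVAL
                scales[name] = float(np.clip(
                    scales[name] * np.exp(0.6 * (rate - _TARGET_ACCEPT)), 1e-3, 10.0
                ))
                acc_window[name] = 0

        # --- latent states from exact full conditionals ------------------
        psi = inv(arr.X_psi @ beta)
        theta = inv(arr.W_theta @ alpha)
        eta_p = arr.V_p @ delta
        p = inv(eta_p)
        logq0 = np.bincount(obs_idx, weights=logF(-eta_p[obs_mask]),
                            minlength=n_samples)
        q0 = np.exp(logq0)  # P(no detection in sample | a = 1)

        # z | a: forced occupied if any a = 1; else odds vs all samples empty
        any_a = np.bincount(arr.sample_site, weights=a, minlength=n_sites) > 0
        log_prod_1m_theta = np.bincount(
            arr.sample_site, weights=logF(-(arr.W_theta @ alpha)),
            minlength=n_sites)
        num = psi * np.exp(log_prod_1m_theta)
        pz = np.where(any_a, 1.0, num / (num + (1 - psi)))
        z = (rng.random(n_sites) < pz).astype(np.int8)
        z[any_a] = 1

        # a | z, y: forced where a detection was observed; impossible if z=0
        num_a = theta * q0
        pa = num_a / (num_a + (1 - theta))
        pa = np.where(arr.det_sample, 1.0, pa)
        pa = np.where(z[arr.sample_site] == 1, pa, 0.0)
        a = (rng.random(n_samples) < pa).astype(np.int8)

        cur_ll["psi"] = _block_loglik_psi(beta, arr, z, config.link)
        cur_ll["theta"] = _block_loglik_theta(alpha, arr, z, a, config.link)
        cur_ll["p"] = _block_loglik_p(delta, arr, a, config.link)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and m < M:
            out_beta[m] = beta
            out_alpha[m] = alpha
            out_delta[m] = delta
            out_z[m] = z
            out_a[m] = a
            m += 1

    rates = {k: acc[k] / config.iterations for k in acc}
    if min(rates.values()) < 0.05 or max(rates.values()) > 0.9:
        warnings.warn(f"extreme Metropolis acceptance rates {rates}; "
                      "inspect traces before trusting summaries", stacklevel=2)

    return PosteriorDraws(
        beta_psi=out_beta[:m], alpha_theta=out_alpha[:m], delta_p=out_delta[:m],
        z=out_z[:m], a=out_a[:m], spec=spec, config=config, arrays=arr,
        accept_rates=rates,
    )


# ---------------------------------------------------------------------------
def summarize(draws: np.ndarray | pd.DataFrame, names: Sequence[str] | None = None,
              transform: Callable[[np.ndarray], np.ndarray] | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, median, equal-tailed 95% CRI, MCSE.

    ``draws`` is (M,) or (M, k); an optional monotone ``transform`` (e.g.
    the inverse link) is applied per draw before summarizing.  MCSE of the
    posterior mean uses non-overlapping batch means with ~sqrt(M) batches.
    """
    if isinstance(draws, pd.DataFrame):
        names = list(draws.columns) if names is None else list(names)
        draws = draws.to_numpy()
    draws = np.asarray(draws, float)
    if draws.ndim == 1:
        draws = draws[:, None]
    M, k = draws.shape
    if M == 0:
        raise ValueError("no posterior draws to summarize")
    if M < 100:
        warnings.warn("fewer than 100 retained draws; summaries will be noisy",
                      stacklevel=2)
    if transform is not None:
        draws = np.asarray(transform(draws), float)

    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    summary = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "median": med,
            "cri_lower": lo,
            "cri_upper": hi,
            "mcse": [_batch_means_mcse(draws[:, j]) for j in range(k)],
        },
        index=list(names) if names is not None else range(k),
    )
    return summary


def _batch_means_mcse(x: np.ndarray) -> float:
    n = x.size
    b = max(int(np.floor(np.sqrt(n))), 1)
    nb = n // b
    if nb < 2:
        return float("nan")
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(np.sqrt(means.var(ddof=1) / nb))


def covariate_effect_flag(summary_row: pd.Series | pd.DataFrame) -> bool:
    """True when the 95% CRI of a slope excludes zero (inclusive endpoints)."""
    if isinstance(summary_row, pd.DataFrame):
        if len(summary_row) != 1:
            raise ValueError("pass a single summary row")
        summary_row = summary_row.iloc[0]
    lo, hi = float(summary_row["cri_lower"]), float(summary_row["cri_upper"])
    return not (lo <= 0.0 <= hi)
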