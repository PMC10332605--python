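"""Two-level constant occupancy model fit by maximum likelihood.

The classic single-season model separates the probability a sampling unit
is occupied (psi) from the per-replicate detection probability (p).  For a
unit with d detections in t replicates the likelihood contribution is

    d > 0:  psi * C(t, d) * p**d * (1-p)**(t-d)
    d = 0:  psi * (1-p)**t + (1 - psi)

Units may have different numbers of replicates (ragged designs are the rule
in field data).  The fit is deterministic: the likelihood is maximized on
the logit scale from a small grid of starting values, and standard errors
come from the inverse observed information mapped through the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

__all__ = ["ClassicHistories", "ClassicFit", "classic_loglik", "fit_classic"]

_BOUNDARY_LOGIT = 12.0  # |logit| beyond this is treated as a boundary estimate


@dataclass(frozen=True)
class ClassicHistories:
    """Detection totals per sampling unit: d detections out of t replicates."""

    detections: np.ndarray
    trials: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.detections, dtype=int)
        t = np.asarray(self.trials, dtype=int)
        object.__setattr__(self, "detections", d)
        object.__setattr__(self, "trials", t)
        if d.shape != t.shape or d.ndim != 1:
            raise ValueError("detections and trials must be matching 1-D vectors")
        if (t < 1).any() or (d < 0).any() or (d > t).any():
            raise ValueError("need 0 <= detections <= trials and trials >= 1")

    @classmethod
    def from_dataset(cls, dataset, unit_level: str = "sample") -> "ClassicHistories":
        """Collapse a three-level dataset to two levels.

        ``unit_level='sample'``: unit = water sample, replicate = qPCR run.
        ``unit_level='site'``: unit = site, replicate = water sample (a
        sample counts as one detection if any of its replicates detected).
        Missing replicates are dropped, not counted as trials.
        """
        d, t = [], []
        if unit_level == "sample":
            for site in dataset.detections:
                for y in site:
                    obs = y[~np.isnan(y)]
                    if obs.size:
                        d.append(int(obs.sum()))
                        t.append(obs.size)
        elif unit_level == "site":
            for site in dataset.detections:
                per_sample = [y[~np.isnan(y)] for y in site]
                per_sample = [y for y in per_sample if y.size]
                if per_sample:
                    d.append(sum(int(y.any()) for y in per_sample))
                    t.append(len(per_sample))
        else:
            raise ValueError("unit_level must be 'sample' or 'site'")
        return cls(np.asarray(d), np.asarray(t))


@dataclass(frozen=True)
class ClassicFit:
    psi_hat: float
    p_hat: float
    psi_se: float  # NaN at boundary estimates
    p_se: float
    loglik: float
    converged: bool
    at_boundary: bool = False
    n_units: int = 0


def _log_binom(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    return gammaln(t + 1) - gammaln(d + 1) - gammaln(t - d + 1)


def classic_loglik(psi: float, p: float, histories: ClassicHistories) -> float:
    """Log-likelihood of (psi, p); -inf outside the open unit square."""
    if not (0 < psi < 1 and 0 < p < 1):
        return -np.inf
    d, t = histories.detections, histories.trials
    pos = d > 0
    ll = 0.0
    if pos.any():
        dp, tp = d[pos], t[pos]
        ll += np.sum(
            np.log(psi) + _log_binom(tp, dp) + dp * np.log(p) + (tp - dp) * np.log1p(-p)
        )
    if (~pos).any():
        t0 = t[~pos]
        ll += np.sum(np.log(psi * np.exp(t0 * np.log1p(-p)) + (1 - psi)))
    return float(ll)


def _nll_logit(x: np.ndarray, histories: ClassicHistories) -> float:
    psi, p = expit(x)
    return -classic_loglik(psi, p, histories)


def _hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_classic(histories: ClassicHistories) -> ClassicFit:
    """Maximum-likelihood fit of the constant model psi(.)p(.).

    Optimizes on the logit scale from the 9-point grid psi, p in
    {0.25, 0.5, 0.75}^2 and keeps the best optimum.  SEs are delta-method
    transforms of the inverse logit-scale observed information; they are
    reported as NaN when an estimate sits on the boundary of the parameter
    space (all-detected or all-empty data), where the quadratic
    approximation is meaningless.
    """
    if not (histories.detections > 0).any():
        warnings.warn(
            "no detections in any unit: psi is not identified, reporting boundary fit",
            stacklevel=2,
        )
        return ClassicFit(0.0, np.nan, np.nan, np.nan,
                          loglik=0.0, converged=True, at_boundary=True,
                          n_units=len(histories.trials))

    best = None
    for psi0 in (0.25, 0.5, 0.75):
        for p0 in (0.25, 0.5, 0.75):
            res = minimize(
                _nll_logit, logit([psi0, p0]), args=(histories,),
                method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    x = best.x
    psi_hat, p_hat = expit(x)
    at_boundary = bool(np.abs(x).max() > _BOUNDARY_LOGIT)

    psi_se = p_se = np.nan
    if not at_boundary:
        H = _hessian(lambda xx: _nll_logit(xx, histories), x)
        try:
            cov = np.linalg.inv(H)
            grad = expit(x) * (1 - expit(x))  # d prob / d logit
            se = np.sqrt(np.clip(np.diag(cov), 0, None)) * grad
            psi_se, p_se = float(se[0]), float(se[1])
        except np.linalg.LinAlgError:
            pass

    return ClassicFit(
        psi_hat=float(np.clip(psi_hat, 0, 1)),
        p_hat=float(np.clip(p_hat, 0, 1)),
        psi_se=psi_se,
        p_se=p_se,
        loglik=-float(best.fun),
        converged=bool(best.success or np.linalg.norm(best.jac) < 1e-5),
        at_boundary=at_boundary,
        n_units=len(histories.trials),
    )
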