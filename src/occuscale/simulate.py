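"""Synthetic three-level eDNA survey data under the hierarchical Bernoulli model.

The generator draws the model forward: site occupancy z, conditional sample
capture a, conditional replicate detection y, with covariates drawn from
declared distributions and then standardized exactly as the analysis
pipeline standardizes real covariates — so generating coefficients live on
the same scale as fitted ones.  The true latent states are returned
alongside the data for parameter-recovery and coverage studies.

``field_design()`` reproduces the layout of the ten-site Texas spring
survey (nine sites with six 1 L water samples, one with three; three qPCR
replicates per sample; the published per-site salamander densities as the
sample-level predictor) with the fitted posterior medians as generating
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SurveyDataset, standardize_covariates
from .datasets import field_site_table
from .multiscale import LatentState, ModelSpec, _inv_link

__all__ = ["SimulationParams", "simulate_multiscale", "field_design"]


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for one synthetic survey.

    ``covariates`` maps a covariate name to either an explicit per-site
    value sequence or a distribution spec ``("normal", mean, sd)`` /
    ``("lognormal", mu, sigma)``.  Coefficient vectors are
    (intercept, one slope per covariate named in ``spec``) on the link
    scale, applied to standardized covariates.
    """

    n_sites: int
    samples_per_site: int | Sequence[int]
    replicates_per_sample: int
    beta_psi: tuple[float, ...]
    alpha_theta: tuple[float, ...]
    delta_p: tuple[float, ...]
    seed: int
    spec: ModelSpec = dc_field(default_factory=ModelSpec)
    covariates: Mapping[str, object] = dc_field(default_factory=dict)
    link: str = "probit"

    def __post_init__(self) -> None:
        if len(self.beta_psi) != 1 + len(self.spec.psi):
            raise ValueError("beta_psi length must match psi covariates + intercept")
        if len(self.alpha_theta) != 1 + len(self.spec.theta):
            raise ValueError("alpha_theta length must match theta covariates + intercept")
        if len(self.delta_p) != 1 + len(self.spec.p):
            raise ValueError("delta_p length must match p covariates + intercept")

    def samples_vector(self) -> np.ndarray:
        if np.isscalar(self.samples_per_site):
            return np.full(self.n_sites, int(self.samples_per_site))
        v = np.asarray(self.samples_per_site, int)
        if v.size != self.n_sites:
            raise ValueError("samples_per_site length must equal n_sites")
        return v


def _draw_covariate(rng: np.random.Generator, spec_entry, n: int) -> np.ndarray:
    if isinstance(spec_entry, (list, tuple, np.ndarray)) and not (
        len(spec_entry) and isinstance(spec_entry[0], str)
    ):
        vals = np.asarray(spec_entry, float)
        if vals.size != n:
            raise ValueError("explicit covariate values must have one entry per site")
        return vals
    kind, *params = spec_entry
    if kind == "normal":
        mean, sd = params
        if sd <= 0:
            raise ValueError("normal covariate needs sd > 0")
        return rng.normal(mean, sd, n)
    if kind == "lognormal":
        mu, sigma = params
        if sigma <= 0:
            raise ValueError("lognormal covariate needs sigma > 0")
        return rng.lognormal(mu, sigma, n)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def simulate_multiscale(params: SimulationParams) -> tuple[SurveyDataset, LatentState]:
    """Draw one dataset (and its true latent states) from the model."""
    rng = np.random.default_rng(params.seed)
    n_sites = params.n_sites
    samples = params.samples_vector()
    K = int(params.replicates_per_sample)

    cov_frame = pd.DataFrame(index=[f"site{i + 1}" for i in range(n_sites)])
    for name, entry in params.covariates.items():
        cov_frame[name] = _draw_covariate(rng, entry, n_sites)

    site_ids = list(cov_frame.index)
    sample_ids = [[f"S{j + 1}" for j in range(s)] for s in samples]
    detections = [[np.zeros(K) for _ in range(s)] for s in samples]
    ds = SurveyDataset(site_ids, sample_ids, detections, site_covariates=cov_frame)
    used = {*params.spec.psi, *params.spec.theta, *params.spec.p}
    if used:
        ds = standardize_covariates(ds, sorted(used))

    inv = _inv_link(params.link)

    def lin(names: tuple[str, ...], coef: tuple[float, ...]) -> np.ndarray:
        eta = np.full(n_sites, coef[0], float)
        for c, nm in zip(coef[1:], names):
            eta += c * ds.site_covariate_values(nm)
        return eta

    psi = inv(lin(params.spec.psi, params.beta_psi))
    theta_site = inv(lin(params.spec.theta, params.alpha_theta))
    p_site = inv(lin(params.spec.p, params.delta_p))

    z = (rng.random(n_sites) < psi).astype(np.int8)
    a_flat = []
    for i in range(n_sites):
        a_i = (rng.random(samples[i]) < z[i] * theta_site[i]).astype(np.int8)
        a_flat.extend(a_i.tolist())
        for j in range(samples[i]):
            y = (rng.random(K) < a_i[j] * p_site[i]).astype(float)
            ds.detections[i][j] = y
    return ds, LatentState(z=z, a=np.asarray(a_flat, np.int8))


def field_design(seed: int,
                 beta_psi: tuple[float, ...] = (1.542,),
                 alpha_theta: tuple[float, ...] = (0.452, 1.014),
                 delta_p: tuple[float, ...] = (1.185,)) -> SimulationParams:
    """The ten-site study layout with its fitted posterior medians as truth."""
    table = field_site_table()
    return SimulationParams(
        n_sites=len(table),
        samples_per_site=table["n_samples"].tolist(),
        replicates_per_sample=3,
        beta_psi=beta_psi,
        alpha_theta=alpha_theta,
        delta_p=delta_p,
        seed=seed,
        spec=ModelSpec(theta=("density",)),
        covariates={"density": table["density"].to_numpy()},
        link="probit",
    )
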