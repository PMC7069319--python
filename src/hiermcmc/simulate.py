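"""Synthetic-data generators emulating the four case-study survey designs.

Each generator draws latent states and observations from the exact model its
builder fits, returns the generating parameter values as ground truth, and
reports realized tallies (possible detections, latent states a sampled-latent
MCMC would have to update).  Designs follow the case-study summary table:

* single-species dynamic occupancy: 100 sites x 15 years x 5 visits
  (7,500 possible detections), simulated at high (p = 0.73) or low
  (p = 0.27) detectability;
* multispecies single-season occupancy: 58 species, 70 sites, 3-4 visits;
* multispecies multiseason occupancy: 49 species, 31 sites, 10 years,
  2-7 visits;
* zero-inflated N-mixture: 267 quadrats surveyed 2-3 times.

Generating values not pinned by the study design (initial occupancy,
persistence, colonization, community hyperparameters) come from the
versioned ``data/sim_defaults.json`` fixture so tests are stable; covariates
are simulated standard normal.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np

from .datatypes import CountData, DetectionData

__all__ = ["SimResult", "sim_defaults", "sim_dynocc", "sim_occ_multisp",
           "sim_dynocc_multisp", "sim_nmix_zip", "simulate_for"]


def sim_defaults() -> dict:
    """The versioned default generating values for all four designs."""
    with resources.files("hiermcmc.data").joinpath("sim_defaults.json").open() as fh:
        return json.load(fh)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass
class SimResult:
    """Simulated data, generating truth, realized design tallies, seed."""

    data: DetectionData | CountData
    truth: dict
    realized: dict
    seed: int


def sim_dynocc(nsite: int = 100, nyear: int = 15, nvisit: int = 5,
               psi1: float | None = None, phi: float | None = None,
               gamma: float | None = None, p: float | None = None,
               scenario: str = "high", seed: int = 0) -> SimResult:
    """Single-species dynamic-occupancy data.

    ``scenario`` selects the high (p = 0.73) or low (p = 0.27) detectability
    generating value unless ``p`` is given explicitly.
    """
    d = sim_defaults()["dynocc_single"]
    psi1 = d["psi1"] if psi1 is None else psi1
    phi = d["phi"] if phi is None else phi
    gamma = d["gamma"] if gamma is None else gamma
    if p is None:
        if scenario not in ("high", "low"):
            raise ValueError("scenario must be 'high' or 'low'")
        p = d["p_high"] if scenario == "high" else d["p_low"]
    for v in (psi1, phi, gamma, p):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = np.empty((nsite, nyear), dtype=int)
    z[:, 0] = rng.random(nsite) < psi1
    for t in range(1, nyear):
        pr = np.where(z[:, t - 1] == 1, phi, gamma)
        z[:, t] = rng.random(nsite) < pr
    y = (rng.random((nsite, nyear, nvisit)) < p * z[:, :, None]).astype(int)
    mask = np.ones_like(y)
    data = DetectionData(y, mask)
    anydet = y.any(axis=2)
    realized = dict(
        possible_detections=nsite * nyear * nvisit,
        detections=int(y.sum()),
        latents_to_sample=int((~anydet).sum()),
        occupied_site_seasons=int(z.sum()),
    )
    truth = dict(psi1=psi1, phi=phi, gamma=gamma, p=p, scenario=scenario)
    return SimResult(data, truth, realized, seed)


def sim_occ_multisp(nspecies: int = 58, nsite: int = 70, nvisit_max: int = 4,
                    n_occ_cov: int = 4, n_det_cov: int = 4,
                    hyper: dict | None = None, seed: int = 0) -> SimResult:
    """Multispecies single-season occupancy data with 3-4 visits per site."""
    d = dict(sim_defaults()["occ_multisp"])
    if hyper:
        d.update(hyper)
    mu_occ = np.asarray(d["mu_occ"], dtype=float)[: n_occ_cov + 1]
    sd_occ = np.asarray(d["sd_occ"], dtype=float)[: n_occ_cov + 1]
    mu_det = np.asarray(d["mu_det"], dtype=float)[: n_det_cov + 1]
    sd_det = np.asarray(d["sd_det"], dtype=float)[: n_det_cov + 1]
    rng = np.random.default_rng(seed)
    x_occ = rng.standard_normal((nsite, n_occ_cov))
    x_det = rng.standard_normal((nsite, nvisit_max, n_det_cov))
    occ_coef = mu_occ[:, None] + sd_occ[:, None] * rng.standard_normal(
        (n_occ_cov + 1, nspecies))
    det_coef = mu_det[:, None] + sd_det[:, None] * rng.standard_normal(
        (n_det_cov + 1, nspecies))
    X1o = np.concatenate([np.ones((nsite, 1)), x_occ], axis=1)
    X1d = np.concatenate([np.ones((nsite, nvisit_max, 1)), x_det], axis=2)
    psi = _expit((X1o @ occ_coef).T)                       # (S, I)
    pdet = _expit(np.einsum("ijk,ks->sij", X1d, det_coef))  # (S, I, J)
    nvisits = rng.integers(nvisit_max - 1, nvisit_max + 1, size=nsite)
    mask_site = (np.arange(nvisit_max)[None, :] < nvisits[:, None]).astype(int)
    mask = np.broadcast_to(mask_site[None], (nspecies, nsite, nvisit_max)).copy()
    z = (rng.random((nspecies, nsite)) < psi).astype(int)
    y = ((rng.random(pdet.shape) < pdet * z[:, :, None]) & (mask == 1)).astype(int)
    data = DetectionData(y, mask, covariates=dict(x_occ=x_occ, x_det=x_det),
                         multispecies=True)
    anydet = y.any(axis=2)
    realized = dict(
        possible_detections=int(mask.sum()),
        detections=int(y.sum()),
        latents_to_sample=int((~anydet).sum()),
        occupied=int(z.sum()),
    )
    truth = dict(mu_occ=mu_occ, sd_occ=sd_occ, mu_det=mu_det, sd_det=sd_det,
                 occ_coef=occ_coef, det_coef=det_coef, z=z)
    return SimResult(data, truth, realized, seed)


def sim_dynocc_multisp(nspecies: int = 49, nsite: int = 31, nyear: int = 10,
                       nvisit_min: int = 2, nvisit_max: int = 7,
                       n_psi_cov: int = 5, n_phi_sp: int = 3, n_phi_sh: int = 3,
                       n_gamma_sp: int = 3, n_gamma_sh: int = 3,
                       n_p_sp: int = 2, n_p_sh: int = 4,
                       hyper: dict | None = None, seed: int = 0) -> SimResult:
    """Multispecies dynamic-occupancy data with 2-7 visits per site-year."""
    d = dict(sim_defaults()["dynocc_multisp"])
    if hyper:
        d.update(hyper)
    rng = np.random.default_rng(seed)
    S, I, T, J = nspecies, nsite, nyear, nvisit_max
    x_psi = rng.standard_normal((I, n_psi_cov))
    x_phi = rng.standard_normal((I, n_phi_sp + n_phi_sh))
    x_gamma = rng.standard_normal((I, n_gamma_sp + n_gamma_sh))
    x_det = rng.standard_normal((I, T, J, n_p_sp + n_p_sh))
    psi1_coef = np.asarray(d["psi1_coef"], dtype=float)[: n_psi_cov + 1]
    phi_sh = np.asarray(d["phi_sh"], dtype=float)[:n_phi_sh]
    gamma_sh = np.asarray(d["gamma_sh"], dtype=float)[:n_gamma_sh]
    p_sh = np.asarray(d["p_sh"], dtype=float)[:n_p_sh]

    def draw_sp(mu_key, sd_key, k):
        mu = np.asarray(d[mu_key], dtype=float)[:k]
        sd = np.asarray(d[sd_key], dtype=float)[:k]
        return mu[:, None] + sd[:, None] * rng.standard_normal((k, S)), mu, sd

    phi_sp, mu_phi, sd_phi = draw_sp("mu_phi", "sd_phi", n_phi_sp + 1)
    gamma_sp, mu_gamma, sd_gamma = draw_sp("mu_gamma", "sd_gamma", n_gamma_sp + 1)
    p_sp, mu_p, sd_p = draw_sp("mu_p", "sd_p", n_p_sp + 1)

    X1psi = np.concatenate([np.ones((I, 1)), x_psi], axis=1)
    psi1 = _expit(X1psi @ psi1_coef)                                     # (I,)
    phi = _expit(phi_sp[0][:, None] + (x_phi[:, :n_phi_sp] @ phi_sp[1:]).T
                 + (x_phi[:, n_phi_sp:] @ phi_sh if n_phi_sh else 0.0))  # (S, I)
    gam = _expit(gamma_sp[0][:, None] + (x_gamma[:, :n_gamma_sp] @ gamma_sp[1:]).T
                 + (x_gamma[:, n_gamma_sp:] @ gamma_sh if n_gamma_sh else 0.0))
    lp = (p_sp[0][:, None, None, None]
          + np.einsum("itjk,ks->sitj", x_det[..., :n_p_sp], p_sp[1:]))
    if n_p_sh:
        lp = lp + np.einsum("itjk,k->itj", x_det[..., n_p_sp:], p_sh)[None]
    pdet = _expit(lp)                                                    # (S,I,T,J)

    nvisits = rng.integers(nvisit_min, nvisit_max + 1, size=(I, T))
    mask_it = (np.arange(J)[None, None, :] < nvisits[:, :, None]).astype(int)
    mask = np.broadcast_to(mask_it[None], (S, I, T, J)).copy()

    z = np.empty((S, I, T), dtype=int)
    z[:, :, 0] = rng.random((S, I)) < psi1[None, :]
    for t in range(1, T):
        pr = np.where(z[:, :, t - 1] == 1, phi, gam)
        z[:, :, t] = rng.random((S, I)) < pr
    y = ((rng.random(pdet.shape) < pdet * z[..., None]) & (mask == 1)).astype(int)
    data = DetectionData(
        y, mask, multispecies=True,
        covariates=dict(x_psi=x_psi, x_phi=x_phi, x_gamma=x_gamma, x_det=x_det))
    anydet = y.any(axis=3)
    realized = dict(
        possible_detections=int(mask.sum()),
        detections=int(y.sum()),
        latents_to_sample=int((~anydet).sum()),
        occupied=int(z.sum()),
    )
    truth = dict(psi1_coef=psi1_coef, phi_sh=phi_sh, gamma_sh=gamma_sh, p_sh=p_sh,
                 mu_phi=mu_phi, sd_phi=sd_phi, mu_gamma=mu_gamma,
                 sd_gamma=sd_gamma, mu_p=mu_p, sd_p=sd_p,
                 phi_sp=phi_sp, gamma_sp=gamma_sp, p_sp=p_sp, z=z)
    return SimResult(data, truth, realized, seed)


def sim_nmix_zip(nsite: int = 267, nvisit_min: int = 2, nvisit_max: int = 3,
                 n_abund_cov: int = 9, n_det_cov: int = 13,
                 theta: float | None = None, hierarchical: bool = False,
                 truth_over: dict | None = None, seed: int = 0) -> SimResult:
    """Zero-inflated N-mixture count data over quadrats with 2-3 surveys."""
    d = dict(sim_defaults()["nmix_zip"])
    if truth_over:
        d.update(truth_over)
    theta = d["theta"] if theta is None else theta
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    I, J = nsite, nvisit_max
    x_lam = rng.standard_normal((I, n_abund_cov))
    x_det = rng.standard_normal((I, J, n_det_cov))
    lam_coef = np.asarray(d["lam_coef"], dtype=float)[: n_abund_cov + 1]
    det_coef = np.asarray(d["det_coef"], dtype=float)[: n_det_cov + 1]
    X1a = np.concatenate([np.ones((I, 1)), x_lam], axis=1)
    X1d = np.concatenate([np.ones((I, J, 1)), x_det], axis=2)
    loglam = X1a @ lam_coef
    logitp = np.einsum("ijk,k->ij", X1d, det_coef)
    truth = dict(theta=theta, lam_coef=lam_coef, det_coef=det_coef)
    if hierarchical:
        eps_lam = d["sd_lam_site"] * rng.standard_normal(I)
        eps_p_site = d["sd_p_site"] * rng.standard_normal(I)
        eps_p_survey = d["sd_p_survey"] * rng.standard_normal((I, J))
        loglam = loglam + eps_lam
        logitp = logitp + eps_p_site[:, None] + eps_p_survey
        truth.update(sd_lam_site=d["sd_lam_site"], sd_p_site=d["sd_p_site"],
                     sd_p_survey=d["sd_p_survey"], eps_lam=eps_lam,
                     eps_p_site=eps_p_site, eps_p_survey=eps_p_survey)
    lam = np.exp(loglam)
    pdet = _expit(logitp)
    suit = (rng.random(I) < theta).astype(int)
    N = rng.poisson(lam * suit)
    y = rng.binomial(N[:, None], pdet)
    nvisits = rng.integers(nvisit_min, nvisit_max + 1, size=I)
    mask = (np.arange(J)[None, :] < nvisits[:, None]).astype(int)
    y = y * mask
    data = CountData(y, mask, covariates=dict(x_lam=x_lam, x_det=x_det))
    anydet = (y > 0).any(axis=1)
    realized = dict(
        possible_detections=int(mask.sum()),
        total_count=int(y.sum()),
        latents_to_sample=int((~anydet).sum()) + I,
        suitable=int(suit.sum()),
    )
    truth.update(suit=suit, N=N)
    return SimResult(data, truth, realized, seed)


def simulate_for(config, seed: int = 0, scenario: str = "high") -> SimResult:
    """Simulate a dataset matching a :class:`~hiermcmc.case_models.ModelConfig`."""
    k = config.model_kind
    if k == "dynocc_single":
        return sim_dynocc(config.nsite, config.nyear, config.nvisit,
                          scenario=scenario, seed=seed)
    if k == "occ_multisp":
        return sim_occ_multisp(config.nspecies, config.nsite, config.nvisit,
                               config.n_occ_cov, config.n_det_cov, seed=seed)
    if k == "dynocc_multisp":
        return sim_dynocc_multisp(
            config.nspecies, config.nsite, config.nyear,
            nvisit_max=config.nvisit,
            n_psi_cov=config.n_psi_cov, n_phi_sp=config.n_phi_sp,
            n_phi_sh=config.n_phi_sh, n_gamma_sp=config.n_gamma_sp,
            n_gamma_sh=config.n_gamma_sh, n_p_sp=config.n_p_sp,
            n_p_sh=config.n_p_sh, seed=seed)
    if k == "nmix_zip":
        return sim_nmix_zip(config.nsite, nvisit_max=config.nvisit,
                            n_abund_cov=config.n_abund_cov,
                            n_det_cov=config.n_nmix_det_cov,
                            hierarchical=config.hierarchical, seed=seed)
    raise ValueError(f"unknown model kind {k!r}")
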