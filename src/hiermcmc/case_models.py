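"""Builders for the four case-study model families.

Each family comes in {more hierarchical (+H), less hierarchical (-H)} x
{latent states sampled, latent states integrated} variants:

* ``dynocc_single`` — single-species multiseason (dynamic) occupancy with
  year-specific persistence/colonization/detection (+H) or constant rates
  (-H); top-level parameter counts 7 / 4.
* ``occ_multisp`` — multispecies single-season occupancy with
  species-specific occupancy and detection coefficients drawn from community
  distributions (+H) or shared across species (-H); counts 20 / 10.
* ``dynocc_multisp`` — multispecies multiseason occupancy with
  covariate-dependent persistence, colonization and detection; 38 / 27.
* ``nmix_zip`` — zero-inflated N-mixture abundance model; +H adds site and
  survey random effects with three extra sd hyperparameters; 28 / 25.

Hierarchical unit-specific effects are placed on the logit scale with
Normal(mean, sd) common distributions.  Priors follow the package defaults:
nearly flat normals (sd 100) on location hyperparameters, Uniform(0, 100) on
sd hyperparameters, Uniform(0, 1) on probability-scale scalars, and narrower
Normal(0, 10) coefficient priors for the N-mixture family.

In latent-state-sampled variants, any latent that is forced by the data
(a detected site-season implies occupancy; a positive count implies
suitability) is treated as data and not sampled, which is why sampled-latent
tallies fall below the number of site-seasons.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import expit, gammaln

from .datatypes import CountData, DetectionData
from .marginal_lik import (
    NEG_INF,
    _forward,
    dynocc_marginal_ll_sites,
    nmix_range,
    nmix_zip_marginal_ll,
)
from .model_core import (
    ConfigurationError,
    HierModel,
    LogDensityTerm,
    ParamSpec,
    PriorSpec,
    Support,
)

__all__ = ["ModelConfig", "build_model", "build_dynocc_single",
           "build_occ_multisp", "build_dynocc_multisp", "build_nmix_zip",
           "default_priors", "MODEL_KINDS"]

MODEL_KINDS = ("dynocc_single", "occ_multisp", "dynocc_multisp", "nmix_zip")

_LOG2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass
class ModelConfig:
    """Model-family configuration: variant flags, dimensions, covariate counts."""

    model_kind: str
    hierarchical: bool = True
    marginalize: bool = True
    nsite: int = 100
    nyear: int = 15
    nvisit: int = 5
    nspecies: int = 1
    # covariate counts (defaults reproduce the declared top-level totals)
    n_occ_cov: int = 4      # occ_multisp occupancy slopes
    n_det_cov: int = 4      # occ_multisp detection slopes
    n_psi_cov: int = 5      # dynocc_multisp initial-occupancy slopes
    n_phi_sp: int = 3       # dynocc_multisp species-specific persistence slopes
    n_phi_sh: int = 3       # dynocc_multisp shared persistence slopes
    n_gamma_sp: int = 3
    n_gamma_sh: int = 3
    n_p_sp: int = 2
    n_p_sh: int = 4
    n_abund_cov: int = 9    # nmix abundance slopes
    n_nmix_det_cov: int = 13

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.model_kind!r}")
        for f in ("nsite", "nyear", "nvisit", "nspecies"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be positive")

    @classmethod
    def for_kind(cls, model_kind: str, **over) -> "ModelConfig":
        """Config with the design dimensions of the corresponding case study."""
        dims = {
            "dynocc_single": dict(nsite=100, nyear=15, nvisit=5, nspecies=1),
            "occ_multisp": dict(nsite=70, nyear=1, nvisit=4, nspecies=58),
            "dynocc_multisp": dict(nsite=31, nyear=10, nvisit=7, nspecies=49),
            "nmix_zip": dict(nsite=267, nyear=1, nvisit=3, nspecies=1),
        }[model_kind]
        dims.update(over)
        return cls(model_kind=model_kind, **dims)

    def declared_top_level(self) -> int:
        if self.model_kind == "dynocc_single":
            return 7 if self.hierarchical else 4
        if self.model_kind == "occ_multisp":
            base = (self.n_occ_cov + 1) + (self.n_det_cov + 1)
            return 2 * base if self.hierarchical else base
        if self.model_kind == "dynocc_multisp":
            shared = ((self.n_psi_cov + 1) + self.n_phi_sh + self.n_gamma_sh
                      + self.n_p_sh)
            hier = (self.n_phi_sp + 1) + (self.n_gamma_sp + 1) + (self.n_p_sp + 1)
            return shared + (2 * hier if self.hierarchical else hier)
        if self.model_kind == "nmix_zip":
            base = 1 + (self.n_abund_cov + 1) + (self.n_nmix_det_cov + 1)
            return base + (3 if self.hierarchical else 0)
        raise ConfigurationError(self.model_kind)


def default_priors(model_kind: str) -> dict:
    """Default prior descriptors per parameter class for a model family."""
    priors = {
        "mean": PriorSpec.normal(0.0, 100.0),
        "sd": PriorSpec.uniform(0.0, 100.0),
        "prob": PriorSpec.uniform(0.0, 1.0),
        "coef": PriorSpec.normal(0.0, 100.0),
    }
    if model_kind == "nmix_zip":
        # narrower coefficient priors for the N-mixture family
        priors["coef"] = PriorSpec.normal(0.0, 10.0)
        priors["mean"] = PriorSpec.normal(0.0, 10.0)
    return priors


# ---------------------------------------------------------------------------
# scalar pmf helpers for latent-state terms (hot path: plain math, no scipy)


def _bern_counts_ll(k: float, n: float, p: float) -> float:
    """k detections in n trials at probability p (no binomial coefficient)."""
    if p <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else NEG_INF
    return k * math.log(p) + (n - k) * math.log1p(-p)


def _binom_logpmf(y: int, n: int, p: float) -> float:
    if y > n or y < 0:
        return NEG_INF
    if p <= 0.0:
        return 0.0 if y == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if y == n else NEG_INF
    return (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * math.log(p) + (n - y) * math.log1p(-p))


def _pois_logpmf(n: int, mu: float) -> float:
    if mu <= 0.0:
        return 0.0 if n == 0 else NEG_INF
    return n * math.log(mu) - mu - gammaln(n + 1)


def _lbern(z: float, p: float) -> float:
    if p <= 0.0:
        return 0.0 if z == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if z == 1 else NEG_INF
    return math.log(p) if z == 1 else math.log1p(-p)


# ---------------------------------------------------------------------------
# prior-term constructors


def _normal_prior_term(name: str, mean: float, sd: float) -> LogDensityTerm:
    def ev(v, _m=mean, _s=sd, _n=name):
        x = v[_n]
        return float(-0.5 * np.sum(((x - _m) / _s) ** 2)
                     - x.size * (math.log(_s) + 0.5 * _LOG2PI))
    return LogDensityTerm(f"prior:{name}", (name,), ev)


def _uniform_prior_term(name: str, lo: float, hi: float) -> LogDensityTerm:
    def ev(v, _n=name, _c=-math.log(hi - lo), _lo=lo, _hi=hi):
        x = v[_n]
        if np.any((x < _lo) | (x > _hi)):
            return NEG_INF
        return _c * x.size
    return LogDensityTerm(f"prior:{name}", (name,), ev)


def _hier_normal_term(name: str, mu_name: str, sd_name: str) -> LogDensityTerm:
    """x[k, ...] ~ Normal(mu[k], sd[k]) with sampled hyperparameters."""
    def ev(v, _n=name, _mu=mu_name, _sd=sd_name):
        x = np.asarray(v[_n])
        mu = np.asarray(v[_mu])
        sd = np.asarray(v[_sd])
        if np.any(sd <= 0):
            return NEG_INF
        pad = (1,) * (x.ndim - mu.ndim)
        mu = mu.reshape(mu.shape + pad)
        sd = sd.reshape(sd.shape + pad)
        rep = x.size // max(sd.size, 1)
        return float(-0.5 * np.sum(((x - mu) / sd) ** 2)
                     - rep * np.sum(np.log(sd)) - 0.5 * x.size * _LOG2PI)
    return LogDensityTerm(f"prior:{name}", (name, mu_name, sd_name), ev)


def _zero_normal_term(name: str, sd_name: str) -> LogDensityTerm:
    """x ~ Normal(0, sd) random effects with a sampled sd hyperparameter."""
    def ev(v, _n=name, _sd=sd_name):
        x = np.asarray(v[_n])
        sd = float(np.asarray(v[_sd]).reshape(()))
        if sd <= 0:
            return NEG_INF
        return float(-0.5 * np.sum((x / sd) ** 2)
                     - x.size * (math.log(sd) + 0.5 * _LOG2PI))
    return LogDensityTerm(f"prior:{name}", (name, sd_name), ev)


def _prior_term_for(spec: ParamSpec) -> LogDensityTerm:
    pr = spec.prior
    if pr is None:
        raise ConfigurationError(f"{spec.name!r} has no prior")
    if pr.family == "normal":
        return _normal_prior_term(spec.name, pr.param("mean"), pr.param("sd"))
    if pr.family == "uniform":
        return _uniform_prior_term(spec.name, pr.param("lo"), pr.param("hi"))
    raise ConfigurationError(f"unsupported prior family {pr.family!r}")


def _col_idx(k_rows: int, nspecies: int, s: int) -> np.ndarray:
    """Flat indices of column s of a (k_rows, nspecies) array."""
    return np.arange(k_rows) * nspecies + s


# ---------------------------------------------------------------------------
# single-species multiseason (dynamic) occupancy


def build_dynocc_single(config: ModelConfig, data: DetectionData) -> HierModel:
    """Dynamic occupancy: colonization and persistence of one species over years."""
    y, mask = data.y, data.mask
    I, T, J = config.nsite, config.nyear, config.nvisit
    if y.shape != (I, T, J):
        raise ConfigurationError(f"data shape {y.shape} != config dims {(I, T, J)}")
    det = (y * mask).sum(axis=2).astype(float)        # detections per site-season
    vis = mask.sum(axis=2).astype(float)              # visits per site-season
    anydet = det > 0
    priors = default_priors("dynocc_single")
    H = config.hierarchical

    params = [ParamSpec("psi1", (), Support.unit_interval(), priors["prob"])]
    terms = [_prior_term_for(params[0])]
    if H:
        for base in ("phi", "gamma", "p"):
            params.append(ParamSpec(f"mu_{base}", (), Support.real(), priors["mean"]))
            params.append(ParamSpec(f"sd_{base}", (), Support.interval(0.0, 100.0),
                                    priors["sd"]))
            terms.append(_prior_term_for(params[-2]))
            terms.append(_prior_term_for(params[-1]))
        params.append(ParamSpec("lphi", (T - 1,), Support.real(), role="random"))
        params.append(ParamSpec("lgamma", (T - 1,), Support.real(), role="random"))
        params.append(ParamSpec("lp", (T,), Support.real(), role="random"))
        terms.append(_hier_normal_term("lphi", "mu_phi", "sd_phi"))
        terms.append(_hier_normal_term("lgamma", "mu_gamma", "sd_gamma"))
        terms.append(_hier_normal_term("lp", "mu_p", "sd_p"))

        def rates(v):
            return expit(v["lphi"]), expit(v["lgamma"]), expit(v["lp"])

        rate_inputs = ("lphi", "lgamma", "lp")
        blocks = [[("lphi", t), ("lgamma", t)] for t in range(T - 1)]
    else:
        for nm in ("phi", "gamma", "p"):
            params.append(ParamSpec(nm, (), Support.unit_interval(), priors["prob"]))
            terms.append(_prior_term_for(params[-1]))

        def rates(v):
            return (np.broadcast_to(v["phi"], (T - 1,)),
                    np.broadcast_to(v["gamma"], (T - 1,)),
                    np.broadcast_to(v["p"], (T,)))

        rate_inputs = ("phi", "gamma", "p")
        blocks = [[("phi", 0), ("gamma", 0)]]

    if config.marginalize:
        def lik(v, _det=det, _vis=vis):
            phi, gamma, p = rates(v)
            psi1 = float(v["psi1"])
            ll = dynocc_marginal_ll_sites(_det, _vis, psi1, phi, gamma, p)
            return float(ll.sum())

        terms.append(LogDensityTerm("lik", ("psi1",) + rate_inputs, lik,
                                    data_slice="all sites"))
        nfree = 0
    else:
        free = ~anydet
        nfree = int(free.sum())
        zindex = -np.ones((I, T), dtype=int)
        zindex[free] = np.arange(nfree)
        params.append(ParamSpec("z", (nfree,), Support.binary(), role="latent"))

        def zval(v, i, t, _zi=zindex, _ad=anydet):
            k = _zi[i, t]
            return 1.0 if k < 0 else float(v["z"].flat[k])

        def get_rate(v, nm, t):
            if H:
                return float(expit(v["l" + nm][t])) if nm != "p" else float(
                    expit(v["lp"][t]))
            return float(v[nm])

        for i in range(I):
            zk0 = zindex[i, 0]
            z_in = {"z": [zk0]} if zk0 >= 0 else None

            def init_ev(v, _i=i):
                return _lbern(zval(v, _i, 0), float(v["psi1"]))

            terms.append(LogDensityTerm(
                f"state:init[{i}]", ("psi1",) + (("z",) if zk0 >= 0 else ()),
                init_ev, indexed_inputs=z_in))
            for t in range(T - 1):
                zk = [k for k in (zindex[i, t], zindex[i, t + 1]) if k >= 0]
                if H:
                    inp = ("lphi", "lgamma") + (("z",) if zk else ())
                    iidx = {"lphi": [t], "lgamma": [t]}
                else:
                    inp = ("phi", "gamma") + (("z",) if zk else ())
                    iidx = {}
                if zk:
                    iidx = dict(iidx, z=zk)

                def trans_ev(v, _i=i, _t=t):
                    z0 = zval(v, _i, _t)
                    z1 = zval(v, _i, _t + 1)
                    rate = (get_rate(v, "phi", _t) if z0 == 1
                            else get_rate(v, "gamma", _t))
                    return _lbern(z1, rate)

                terms.append(LogDensityTerm(
                    f"state:trans[{i},{t}]", inp, trans_ev,
                    indexed_inputs=iidx or None))
            for t in range(T):
                if vis[i, t] == 0:
                    continue
                zk = zindex[i, t]
                if H:
                    inp = ("lp",) + (("z",) if zk >= 0 else ())
                    iidx = {"lp": [t]}
                else:
                    inp = ("p",) + (("z",) if zk >= 0 else ())
                    iidx = {}
                if zk >= 0:
                    iidx = dict(iidx, z=[zk])

                def em_ev(v, _i=i, _t=t, _d=float(det[i, t]), _n=float(vis[i, t])):
                    if zval(v, _i, _t) == 0:
                        return 0.0 if _d == 0 else NEG_INF
                    return _bern_counts_ll(_d, _n, get_rate(v, "p", _t))

                terms.append(LogDensityTerm(
                    f"obs:em[{i},{t}]", inp, em_ev, indexed_inputs=iidx or None,
                    data_slice=f"site {i}, season {t}"))

    meta = dict(model_kind="dynocc_single", hierarchical=H,
                marginalize=config.marginalize, dims=(I, T, J),
                latents_to_sample=(0 if config.marginalize else nfree))
    return HierModel(params, terms, data=data, block_groups=blocks, meta=meta,
                     declared_top_level=config.declared_top_level())


# ---------------------------------------------------------------------------
# multispecies single-season occupancy


def build_occ_multisp(config: ModelConfig, data: DetectionData) -> HierModel:
    y, mask = data.y, data.mask
    S, I, J = config.nspecies, config.nsite, config.nvisit
    if y.shape != (S, I, J):
        raise ConfigurationError(f"data shape {y.shape} != config dims {(S, I, J)}")
    Ko, Kd = config.n_occ_cov, config.n_det_cov
    x_occ = np.asarray(data.covariates["x_occ"], dtype=float)   # (I, Ko)
    x_det = np.asarray(data.covariates["x_det"], dtype=float)   # (I, J, Kd)
    if x_occ.shape != (I, Ko) or x_det.shape != (I, J, Kd):
        raise ConfigurationError("covariate shapes inconsistent with config")
    X1o = np.concatenate([np.ones((I, 1)), x_occ], axis=1)       # (I, Ko+1)
    X1d = np.concatenate([np.ones((I, J, 1)), x_det], axis=2)    # (I, J, Kd+1)
    priors = default_priors("occ_multisp")
    H = config.hierarchical
    anydet = ((y * mask) > 0).any(axis=2)  # (S, I)

    params, terms = [], []
    if H:
        for nm, K in (("occ", Ko), ("det", Kd)):
            params.append(ParamSpec(f"mu_{nm}", (K + 1,), Support.real(),
                                    priors["mean"]))
            params.append(ParamSpec(f"sd_{nm}", (K + 1,),
                                    Support.interval(0.0, 100.0), priors["sd"]))
            terms.append(_prior_term_for(params[-2]))
            terms.append(_prior_term_for(params[-1]))
            params.append(ParamSpec(f"{nm}_coef", (K + 1, S), Support.real(),
                                    role="random"))
            terms.append(_hier_normal_term(f"{nm}_coef", f"mu_{nm}", f"sd_{nm}"))

        def species_coef(v, nm, s):
            return v[f"{nm}_coef"][:, s]

        blocks = [
            [("occ_coef", int(k)) for k in _col_idx(Ko + 1, S, s)]
            + [("det_coef", int(k)) for k in _col_idx(Kd + 1, S, s)]
            for s in range(S)
        ]
    else:
        for nm, K in (("occ", Ko), ("det", Kd)):
            params.append(ParamSpec(f"{nm}_coef", (K + 1,), Support.real(),
                                    priors["coef"]))
            terms.append(_prior_term_for(params[-1]))

        def species_coef(v, nm, s):
            return v[f"{nm}_coef"]

        blocks = [[("occ_coef", k) for k in range(Ko + 1)]
                  + [("det_coef", k) for k in range(Kd + 1)]]

    def _lin_preds(v):
        oc, dc = v["occ_coef"], v["det_coef"]
        if H:
            lpsi = (X1o @ oc).T                     # (S, I)
            lp = np.einsum("ijk,ks->sij", X1d, dc)  # (S, I, J)
        else:
            lpsi = np.broadcast_to(X1o @ oc, (S, I))
            lp = np.broadcast_to(np.einsum("ijk,k->ij", X1d, dc), (S, I, J))
        return lpsi, lp

    if config.marginalize:
        ydat = (y * mask).astype(float)

        def lik(v):
            lpsi, lp = _lin_preds(v)
            psi = expit(lpsi)
            p = expit(lp)
            with np.errstate(divide="ignore", invalid="ignore"):
                d1 = np.where(mask.astype(bool),
                              np.where(ydat > 0, np.log(p), np.log1p(-p)), 0.0)
                ll1 = np.log(psi) + d1.sum(axis=2)
                ll0 = np.where(anydet, NEG_INF, np.log1p(-psi))
            return float(np.logaddexp(ll1, ll0).sum())

        terms.append(LogDensityTerm("lik", ("occ_coef", "det_coef"), lik,
                                    data_slice="all species x sites"))
        nfree = 0
    else:
        free = ~anydet
        nfree = int(free.sum())
        zindex = -np.ones((S, I), dtype=int)
        zindex[free] = np.arange(nfree)
        params.append(ParamSpec("z", (nfree,), Support.binary(), role="latent"))
        occ_cols = {s: [int(k) for k in _col_idx(Ko + 1, S, s)] for s in range(S)}
        det_cols = {s: [int(k) for k in _col_idx(Kd + 1, S, s)] for s in range(S)}
        for s in range(S):
            for i in range(I):
                zk = zindex[s, i]

                def zv(v, _zk=zk, _s=s, _i=i):
                    return 1.0 if _zk < 0 else float(v["z"].flat[_zk])

                def state_ev(v, _s=s, _i=i, _zv=zv):
                    psi = float(expit(X1o[_i] @ species_coef(v, "occ", _s)))
                    return _lbern(_zv(v), psi)

                iidx_o = ({"occ_coef": occ_cols[s]} if H else {})
                if zk >= 0:
                    iidx_o = dict(iidx_o, z=[zk])
                terms.append(LogDensityTerm(
                    f"state[{s},{i}]",
                    ("occ_coef",) + (("z",) if zk >= 0 else ()),
                    state_ev, indexed_inputs=iidx_o or None))

                mrow = mask[s, i]
                if mrow.sum() == 0:
                    continue
                yrow = y[s, i]

                def em_ev(v, _s=s, _i=i, _zv=zv, _y=yrow, _m=mrow):
                    if _zv(v) == 0:
                        return 0.0  # free implies no detections
                    p = expit(X1d[_i] @ species_coef(v, "det", _s))
                    tot = 0.0
                    for j in range(J):
                        if _m[j]:
                            tot += _lbern(float(_y[j]), float(p[j]))
                    return tot

                iidx_d = ({"det_coef": det_cols[s]} if H else {})
                if zk >= 0:
                    iidx_d = dict(iidx_d, z=[zk])
                terms.append(LogDensityTerm(
                    f"obs[{s},{i}]",
                    ("det_coef",) + (("z",) if zk >= 0 else ()),
                    em_ev, indexed_inputs=iidx_d or None,
                    data_slice=f"species {s}, site {i}"))

    meta = dict(model_kind="occ_multisp", hierarchical=H,
                marginalize=config.marginalize, dims=(S, I, J),
                latents_to_sample=(0 if config.marginalize else nfree))
    return HierModel(params, terms, data=data, block_groups=blocks, meta=meta,
                     declared_top_level=config.declared_top_level())


# ---------------------------------------------------------------------------
# multispecies multiseason occupancy


def build_dynocc_multisp(config: ModelConfig, data: DetectionData) -> HierModel:
    y, mask = data.y, data.mask
    S, I, T, J = config.nspecies, config.nsite, config.nyear, config.nvisit
    if y.shape != (S, I, T, J):
        raise ConfigurationError(
            f"data shape {y.shape} != config dims {(S, I, T, J)}")
    c = config
    x_psi = np.asarray(data.covariates["x_psi"], dtype=float)    # (I, n_psi_cov)
    x_phi = np.asarray(data.covariates["x_phi"], dtype=float)    # (I, sp+sh)
    x_gamma = np.asarray(data.covariates["x_gamma"], dtype=float)
    x_det = np.asarray(data.covariates["x_det"], dtype=float)    # (I,T,J, sp+sh)
    if (x_psi.shape != (I, c.n_psi_cov)
            or x_phi.shape != (I, c.n_phi_sp + c.n_phi_sh)
            or x_gamma.shape != (I, c.n_gamma_sp + c.n_gamma_sh)
            or x_det.shape != (I, T, J, c.n_p_sp + c.n_p_sh)):
        raise ConfigurationError("covariate shapes inconsistent with config")
    X1psi = np.concatenate([np.ones((I, 1)), x_psi], axis=1)
    priors = default_priors("dynocc_multisp")
    H = config.hierarchical
    anydet = ((y * mask) > 0).any(axis=3)  # (S, I, T)

    params = [ParamSpec("psi1_coef", (c.n_psi_cov + 1,), Support.real(),
                        priors["coef"])]
    terms = [_prior_term_for(params[0])]
    fam = (("phi", c.n_phi_sp, c.n_phi_sh), ("gamma", c.n_gamma_sp, c.n_gamma_sh),
           ("p", c.n_p_sp, c.n_p_sh))
    for nm, ksp, ksh in fam:
        if ksh:
            params.append(ParamSpec(f"{nm}_sh", (ksh,), Support.real(),
                                    priors["coef"]))
            terms.append(_prior_term_for(params[-1]))
        shape = (ksp + 1, S) if H else (ksp + 1,)
        if H:
            params.append(ParamSpec(f"mu_{nm}", (ksp + 1,), Support.real(),
                                    priors["mean"]))
            params.append(ParamSpec(f"sd_{nm}", (ksp + 1,),
                                    Support.interval(0.0, 100.0), priors["sd"]))
            terms.append(_prior_term_for(params[-2]))
            terms.append(_prior_term_for(params[-1]))
            params.append(ParamSpec(f"{nm}_sp", shape, Support.real(),
                                    role="random"))
            terms.append(_hier_normal_term(f"{nm}_sp", f"mu_{nm}", f"sd_{nm}"))
        else:
            params.append(ParamSpec(f"{nm}_sp", shape, Support.real(),
                                    priors["coef"]))
            terms.append(_prior_term_for(params[-1]))

    def sp_coef(v, nm, s=None):
        arr = v[f"{nm}_sp"]
        if not H:
            return arr
        return arr[:, s] if s is not None else arr

    def _rate_logits(v):
        """Logit-scale phi (S,I), gamma (S,I), p (S,I,T,J), psi1 (I,)."""
        out = {}
        for nm, ksp, ksh, X in (("phi", c.n_phi_sp, c.n_phi_sh, x_phi),
                                ("gamma", c.n_gamma_sp, c.n_gamma_sh, x_gamma)):
            sp = v[f"{nm}_sp"]
            sh = v[f"{nm}_sh"] if ksh else 0.0
            shared = X[:, ksp:] @ sh if ksh else 0.0
            if H:
                out[nm] = (sp[0][None, :].T + (X[:, :ksp] @ sp[1:]).T + shared)
            else:
                out[nm] = np.broadcast_to(sp[0] + X[:, :ksp] @ sp[1:] + shared,
                                          (S, I))
        sp = v["p_sp"]
        sh = v["p_sh"] if c.n_p_sh else 0.0
        shared = (np.einsum("itjk,k->itj", x_det[..., c.n_p_sp:], sh)
                  if c.n_p_sh else 0.0)
        if H:
            own = np.einsum("itjk,ks->sitj", x_det[..., :c.n_p_sp], sp[1:])
            out["p"] = (sp[0][:, None, None, None] + own
                        + (shared[None] if c.n_p_sh else 0.0))
        else:
            out["p"] = np.broadcast_to(
                sp[0] + np.einsum("itjk,k->itj", x_det[..., :c.n_p_sp], sp[1:])
                + shared, (S, I, T, J))
        out["psi1"] = X1psi @ v["psi1_coef"]
        return out

    rate_inputs = tuple(n for n in ("psi1_coef", "phi_sp", "phi_sh", "gamma_sp",
                                    "gamma_sh", "p_sp", "p_sh")
                        if any(p.name == n for p in params))

    if config.marginalize:
        ydat = (y * mask).astype(float)

        def lik(v):
            lg = _rate_logits(v)
            phi = expit(lg["phi"])[..., None]      # (S, I, 1) -> broadcast T-1
            gamma = expit(lg["gamma"])[..., None]
            p = expit(lg["p"])
            psi1 = expit(lg["psi1"])[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                e1 = np.where(mask, np.where(ydat > 0, np.log(p), np.log1p(-p)),
                              0.0).sum(axis=3)
                e0 = np.where(anydet, NEG_INF, 0.0)
                ll = _forward(e1, e0, psi1,
                              np.broadcast_to(phi, (S, I, T - 1)),
                              np.broadcast_to(gamma, (S, I, T - 1)))
            return float(ll.sum())

        terms.append(LogDensityTerm("lik", rate_inputs, lik,
                                    data_slice="all species x sites"))
        nfree = 0
    else:
        free = ~anydet
        nfree = int(free.sum())
        zindex = -np.ones((S, I, T), dtype=int)
        zindex[free] = np.arange(nfree)
        params.append(ParamSpec("z", (nfree,), Support.binary(), role="latent"))
        for s in range(S):
            iidx_base = {}
            if H:
                for nm, ksp, _ in fam:
                    iidx_base[f"{nm}_sp"] = [int(k)
                                             for k in _col_idx(ksp + 1, S, s)]
            for i in range(I):
                zks = [int(zindex[s, i, t]) for t in range(T)]
                zfree = [k for k in zks if k >= 0]

                def traj_ev(v, _s=s, _i=i, _zks=tuple(zks)):
                    psi1 = float(expit(X1psi[_i] @ v["psi1_coef"]))
                    phs = v["phi_sp"][:, _s] if H else v["phi_sp"]
                    gms = v["gamma_sp"][:, _s] if H else v["gamma_sp"]
                    pps = v["p_sp"][:, _s] if H else v["p_sp"]
                    lphi = phs[0] + x_phi[_i, :c.n_phi_sp] @ phs[1:]
                    lgam = gms[0] + x_gamma[_i, :c.n_gamma_sp] @ gms[1:]
                    if c.n_phi_sh:
                        lphi += x_phi[_i, c.n_phi_sp:] @ v["phi_sh"]
                    if c.n_gamma_sh:
                        lgam += x_gamma[_i, c.n_gamma_sp:] @ v["gamma_sh"]
                    phi = float(expit(lphi))
                    gam = float(expit(lgam))
                    tot = 0.0
                    zprev = None
                    for t in range(T):
                        k = _zks[t]
                        z = 1.0 if k < 0 else float(v["z"].flat[k])
                        if t == 0:
                            tot += _lbern(z, psi1)
                        else:
                            tot += _lbern(z, phi if zprev == 1 else gam)
                        if tot == NEG_INF:
                            return NEG_INF
                        if z == 1:
                            lp = (pps[0]
                                  + x_det[_i, t, :, :c.n_p_sp] @ pps[1:])
                            if c.n_p_sh:
                                lp = lp + x_det[_i, t, :, c.n_p_sp:] @ v["p_sh"]
                            p = expit(lp)
                            for j in range(J):
                                if mask[_s, _i, t, j]:
                                    tot += _lbern(float(y[_s, _i, t, j]),
                                                  float(p[j]))
                        elif anydet[_s, _i, t]:
                            return NEG_INF
                        zprev = z
                    return tot

                iidx = dict(iidx_base)
                if zfree:
                    iidx["z"] = zfree
                terms.append(LogDensityTerm(
                    f"traj[{s},{i}]",
                    rate_inputs + (("z",) if zfree else ()),
                    traj_ev, indexed_inputs=iidx or None,
                    data_slice=f"species {s}, site {i}"))

    if H:
        blocks = []
        for s in range(S):
            g = []
            for nm, ksp, _ in fam:
                g += [(f"{nm}_sp", int(k)) for k in _col_idx(ksp + 1, S, s)]
            blocks.append(g)
    else:
        blocks = [[(f"{nm}_sp", k) for nm, ksp, _ in fam for k in range(ksp + 1)]]

    meta = dict(model_kind="dynocc_multisp", hierarchical=H,
                marginalize=config.marginalize, dims=(S, I, T, J),
                latents_to_sample=(0 if config.marginalize else nfree))
    return HierModel(params, terms, data=data, block_groups=blocks, meta=meta,
                     declared_top_level=config.declared_top_level())


# ---------------------------------------------------------------------------
# zero-inflated N-mixture


def build_nmix_zip(config: ModelConfig, data: CountData) -> HierModel:
    y, mask = data.y, data.mask
    I, J = config.nsite, config.nvisit
    if y.shape != (I, J):
        raise ConfigurationError(f"data shape {y.shape} != config dims {(I, J)}")
    Ka, Kd = config.n_abund_cov, config.n_nmix_det_cov
    x_lam = np.asarray(data.covariates["x_lam"], dtype=float)   # (I, Ka)
    x_det = np.asarray(data.covariates["x_det"], dtype=float)   # (I, J, Kd)
    if x_lam.shape != (I, Ka) or x_det.shape != (I, J, Kd):
        raise ConfigurationError("covariate shapes inconsistent with config")
    X1a = np.concatenate([np.ones((I, 1)), x_lam], axis=1)
    X1d = np.concatenate([np.ones((I, J, 1)), x_det], axis=2)
    priors = default_priors("nmix_zip")
    H = config.hierarchical
    anydet = ((y * mask) > 0).any(axis=1)
    maxy = (y * mask).max(axis=1).astype(int)

    params = [
        ParamSpec("theta", (), Support.unit_interval(), priors["prob"]),
        ParamSpec("lam_coef", (Ka + 1,), Support.real(), priors["coef"]),
        ParamSpec("det_coef", (Kd + 1,), Support.real(), priors["coef"]),
    ]
    terms = [_prior_term_for(p) for p in params]
    re_names = ()
    if H:
        for nm, shape in (("sd_lam_site", ()), ("sd_p_site", ()),
                          ("sd_p_survey", ())):
            params.append(ParamSpec(nm, shape, Support.interval(0.0, 100.0),
                                    priors["sd"]))
            terms.append(_prior_term_for(params[-1]))
        params.append(ParamSpec("eps_lam", (I,), Support.real(), role="random"))
        params.append(ParamSpec("eps_p_site", (I,), Support.real(), role="random"))
        params.append(ParamSpec("eps_p_survey", (I, J), Support.real(),
                                role="random"))
        terms.append(_zero_normal_term("eps_lam", "sd_lam_site"))
        terms.append(_zero_normal_term("eps_p_site", "sd_p_site"))
        terms.append(_zero_normal_term("eps_p_survey", "sd_p_survey"))
        re_names = ("eps_lam", "eps_p_site", "eps_p_survey")

    def site_loglam(v, i):
        ll = float(X1a[i] @ v["lam_coef"])
        if H:
            ll += float(v["eps_lam"][i])
        return ll

    def site_logitp(v, i):
        lp = X1d[i] @ v["det_coef"]
        if H:
            lp = lp + float(v["eps_p_site"][i]) + v["eps_p_survey"][i]
        return lp

    def _site_re_idx(i):
        if not H:
            return {}
        return {"eps_lam": [i], "eps_p_site": [i],
                "eps_p_survey": [int(k) for k in i * J + np.arange(J)]}

    if config.marginalize:
        for i in range(I):
            mrow = mask[i].astype(bool)
            yrow = y[i]

            def lik_ev(v, _i=i, _y=yrow, _m=mrow):
                ll = site_loglam(v, _i)
                if ll > 30.0:  # e^30 expected birds on a 1 km^2 plot: impossible
                    return NEG_INF
                lam = math.exp(ll)
                p = expit(site_logitp(v, _i))
                rng_ = nmix_range(_y[_m], lam, p[_m])
                return nmix_zip_marginal_ll(_y[_m], float(v["theta"]), lam,
                                            p[_m], rng_)

            terms.append(LogDensityTerm(
                f"lik[{i}]",
                ("theta", "lam_coef", "det_coef") + re_names,
                lik_ev, indexed_inputs=_site_re_idx(i) or None,
                data_slice=f"site {i}"))
        nfree = 0
    else:
        free = ~anydet
        nfree = int(free.sum())
        sindex = -np.ones(I, dtype=int)
        sindex[free] = np.arange(nfree)
        params.append(ParamSpec("suit", (nfree,), Support.binary(), role="latent"))
        params.append(ParamSpec("N", (I,), Support.nonneg_integer(),
                                role="latent"))

        for i in range(I):
            sk = int(sindex[i])

            def sval(v, _sk=sk):
                return 1.0 if _sk < 0 else float(v["suit"].flat[_sk])

            def suit_ev(v, _sv=sval):
                return _lbern(_sv(v), float(v["theta"]))

            terms.append(LogDensityTerm(
                f"suit[{i}]", ("theta",) + (("suit",) if sk >= 0 else ()),
                suit_ev, indexed_inputs=({"suit": [sk]} if sk >= 0 else None)))

            def abund_ev(v, _i=i, _sv=sval):
                n = int(v["N"][_i])
                if _sv(v) == 0:
                    return 0.0 if n == 0 else NEG_INF
                ll = site_loglam(v, _i)
                if ll > 30.0:
                    return NEG_INF
                return _pois_logpmf(n, math.exp(ll))

            iidx = dict(_site_re_idx(i))
            iidx.pop("eps_p_site", None)
            iidx.pop("eps_p_survey", None)
            iidx["N"] = [i]
            if sk >= 0:
                iidx["suit"] = [sk]
            terms.append(LogDensityTerm(
                f"abund[{i}]",
                ("lam_coef", "N") + (("eps_lam",) if H else ())
                + (("suit",) if sk >= 0 else ()),
                abund_ev, indexed_inputs=iidx))

            mrow = mask[i].astype(bool)
            if not mrow.any():
                continue
            yrow = y[i]

            def det_ev(v, _i=i, _y=yrow, _m=mrow):
                n = int(v["N"][_i])
                p = expit(site_logitp(v, _i))
                tot = 0.0
                for j in range(J):
                    if _m[j]:
                        tot += _binom_logpmf(int(_y[j]), n, float(p[j]))
                        if tot == NEG_INF:
                            return NEG_INF
                return tot

            iidx = dict(_site_re_idx(i))
            iidx.pop("eps_lam", None)
            iidx["N"] = [i]
            terms.append(LogDensityTerm(
                f"det[{i}]",
                ("det_coef", "N")
                + (("eps_p_site", "eps_p_survey") if H else ()),
                det_ev, indexed_inputs=iidx, data_slice=f"site {i}"))

    blocks = [[("lam_coef", k) for k in range(Ka + 1)]]
    meta = dict(model_kind="nmix_zip", hierarchical=H,
                marginalize=config.marginalize, dims=(I, J),
                latents_to_sample=(0 if config.marginalize else nfree + I),
                maxy=maxy)
    return HierModel(params, terms, data=data, block_groups=blocks, meta=meta,
                     declared_top_level=config.declared_top_level())


_BUILDERS = {
    "dynocc_single": build_dynocc_single,
    "occ_multisp": build_occ_multisp,
    "dynocc_multisp": build_dynocc_multisp,
    "nmix_zip": build_nmix_zip,
}


def build_model(config: ModelConfig, data) -> HierModel:
    """Dispatch to the family builder named in the config."""
    return _BUILDERS[config.model_kind](config, data)
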