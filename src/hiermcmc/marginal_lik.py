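"""Latent-state-integrated likelihoods for occupancy and N-mixture models.

Three marginalizations over discrete latent states:

* single-season occupancy: the sum over the two occupancy states of a site,
  ``psi * prod_j Bern(y_j | p_j) + (1 - psi) * 1{no detections}``;
* dynamic (multiseason) occupancy: a two-state hidden-Markov-model forward
  recursion through seasons, with persistence ``phi`` and colonization
  ``gamma`` as the transition probabilities;
* zero-inflated N-mixture: the sum over latent abundance ``N`` of
  ``Pois(N | lambda) * prod_j Binom(y_j | N, p_j)``, bounded by extreme
  Poisson quantiles of ``N - y | y ~ Poisson(lambda * (1 - p))`` and
  accumulated by the closed-form ``N -> N + 1`` term ratio so no factorial is
  recomputed.

All accumulation is in log space (15-season visit products underflow in
linear space).  Missing visits (mask 0) contribute a factor of one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp, xlog1py, xlogy

NEG_INF = float("-inf")

__all__ = [
    "OccHistory",
    "DynOccHistory",
    "NmixSiteData",
    "NRange",
    "occ_marginal_ll",
    "dynocc_marginal_ll",
    "dynocc_marginal_ll_sites",
    "nmix_range",
    "nmix_zip_marginal_ll",
]


@dataclasses.dataclass(frozen=True)
class OccHistory:
    """Binary detections over visits at one site; mask 1 = visit occurred."""

    y: np.ndarray
    mask: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class DynOccHistory:
    """Seasons x visits binary detection matrix at one site."""

    Y: np.ndarray
    mask: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class NmixSiteData:
    """Non-negative repeat counts over visits at one site."""

    counts: np.ndarray
    mask: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class NRange:
    """Inclusive summation bounds for latent abundance."""

    nmin: int
    nmax: int

    def __post_init__(self):
        if not 0 <= self.nmin <= self.nmax:
            raise ValueError(f"invalid NRange [{self.nmin}, {self.nmax}]")


def _as_mask(mask, shape):
    if mask is None:
        return np.ones(shape, dtype=bool)
    return np.asarray(mask).astype(bool)


def _unwrap(obj, field):
    if hasattr(obj, field):
        return np.asarray(getattr(obj, field)), obj.mask
    return np.asarray(obj), None


def occ_marginal_ll(h, psi: float, p, mask=None) -> float:
    """Single-season occupancy likelihood with the latent state summed out.

    ``h`` may be an :class:`OccHistory` or a plain binary vector (with
    ``mask`` passed separately).  ``p`` is scalar or per-visit.
    """
    y, m = _unwrap(h, "y")
    m = _as_mask(mask if m is None else m, y.shape)
    y = y.astype(float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    if np.any(y[~m] != 0):
        raise ValueError("detection recorded on a masked visit")
    if not (0.0 <= psi <= 1.0) or np.any((p < 0) | (p > 1)):
        raise ValueError("psi and p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        det = np.where(m, xlogy(y, p) + xlog1py(1.0 - y, -p), 0.0).sum()
        occ = np.log(psi) + det
        unocc = np.log1p(-psi) if not np.any(y[m] > 0) else NEG_INF
    return float(np.logaddexp(occ, unocc))


def _dynocc_emissions(Y, m, p):
    """Log emission probabilities per season for z=1 and z=0."""
    Y = Y.astype(float)
    p = np.broadcast_to(np.asarray(p, dtype=float), Y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(m, xlogy(Y, p) + xlog1py(1.0 - Y, -p), 0.0).sum(axis=-1)
    anydet = (np.where(m, Y, 0.0) > 0).any(axis=-1)
    e0 = np.where(anydet, NEG_INF, 0.0)
    return e1, e0


def dynocc_marginal_ll(h, psi1: float, phi, gamma, p, mask=None) -> float:
    """Dynamic-occupancy likelihood via the HMM forward sum over one site.

    ``h`` is a :class:`DynOccHistory` or a seasons x visits binary matrix;
    ``phi``/``gamma`` have length ``T - 1``; ``p`` broadcasts to the data
    shape (scalar, per-season column, or per-visit matrix).
    """
    Y, m = _unwrap(h, "Y")
    m = _as_mask(mask if m is None else m, Y.shape)
    if Y.ndim != 2:
        raise ValueError("dynamic occupancy history must be seasons x visits")
    T = Y.shape[0]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (max(T - 1, 0),))
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(T - 1, 0),))
    if np.any(Y[~m] != 0):
        raise ValueError("detection recorded on a masked visit")
    p = np.broadcast_to(np.asarray(p, dtype=float), Y.shape)
    e1, e0 = _dynocc_emissions(Y, m, p)
    with np.errstate(divide="ignore"):
        a0 = np.log1p(-psi1) + e0[0]
        a1 = np.log(psi1) + e1[0]
        for t in range(1, T):
            g, f = gamma[t - 1], phi[t - 1]
            b0 = np.logaddexp(a0 + np.log1p(-g), a1 + np.log1p(-f)) + e0[t]
            b1 = np.logaddexp(a0 + np.log(g), a1 + np.log(f)) + e1[t]
            a0, a1 = b0, b1
    return float(np.logaddexp(a0, a1))


def _forward(e1, e0, psi1, phi, gamma) -> np.ndarray:
    """Two-state HMM forward log-sum given per-season log emissions.

    ``e1``/``e0`` have shape (..., T); ``phi``/``gamma`` broadcast to
    (..., T-1) and ``psi1`` to the leading shape.  Returns log P(data) per
    leading index.
    """
    e1 = np.asarray(e1, dtype=float)
    T = e1.shape[-1]
    lead = np.broadcast_shapes(e1.shape[:-1], np.shape(psi1))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), lead + (max(T - 1, 0),))
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), lead + (max(T - 1, 0),))
    psi1 = np.broadcast_to(np.asarray(psi1, dtype=float), lead)
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = np.log1p(-psi1) + e0[..., 0]
        a1 = np.log(psi1) + e1[..., 0]
        for t in range(1, T):
            g, f = gamma[..., t - 1], phi[..., t - 1]
            b0 = np.logaddexp(a0 + np.log1p(-g), a1 + np.log1p(-f)) + e0[..., t]
            b1 = np.logaddexp(a0 + np.log(g), a1 + np.log(f)) + e1[..., t]
            a0, a1 = b0, b1
    return np.logaddexp(a0, a1)


def dynocc_marginal_ll_sites(det, vis, psi1, phi, gamma, p) -> np.ndarray:
    """Vectorized per-site forward sums from sufficient statistics.

    Valid when detection probability is shared by all visits within a season:
    the emission factor then depends only on the per-season detection count
    ``det[..., t]`` and visit count ``vis[..., t]``.  Leading axes index sites
    (or species x sites); returns one log likelihood per leading index.

    ``psi1`` is scalar or per-site; ``phi``/``gamma`` broadcast to
    ``(..., T-1)`` and ``p`` to ``(..., T)``.
    """
    det = np.asarray(det, dtype=float)
    vis = np.asarray(vis, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), det.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = xlogy(det, p) + xlogy(vis - det, 1.0 - p)
        e0 = np.where(det > 0, NEG_INF, 0.0)
    return _forward(e1, e0, psi1, phi, gamma)


_Q_LO = 1e-5
_Q_HI = 1.0 - 1e-5


def nmix_range(counts, lam: float, p, mask=None) -> NRange:
    """Latent-abundance summation bounds from extreme conditional quantiles.

    Uses the exact conditional ``N - y | y ~ Poisson(lambda * (1 - p))``:
    the lower bound is the smallest ``y_j + Q(1e-5)`` over unmasked visits
    (floored at ``max_j y_j``), the upper bound the largest
    ``y_j + Q(1 - 1e-5)``.
    """
    y, m = _unwrap(counts, "counts")
    m = _as_mask(mask if m is None else m, y.shape)
    if not np.any(m):
        raise ValueError("all visits masked: no observed counts to bound N")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = y[m].astype(int)
    p = np.broadcast_to(np.asarray(p, dtype=float), m.shape)[m]
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    mu = lam * (1.0 - p)
    # Poisson ppf at mu=0 is a point mass at zero
    qlo = np.where(mu > 0, stats.poisson.ppf(_Q_LO, np.maximum(mu, 1e-300)), 0.0)
    qhi = np.where(mu > 0, stats.poisson.ppf(_Q_HI, np.maximum(mu, 1e-300)), 0.0)
    nmin = max(int(y.max()), int(np.min(y + qlo)))
    nmax = max(nmin, int(np.max(y + qhi)))
    return NRange(nmin, nmax)


def nmix_zip_marginal_ll(counts, theta: float, lam: float, p, nrange: NRange,
                         mask=None) -> float:
    """Zero-inflated N-mixture site likelihood with N summed out.

    ``(1 - theta) * 1{all y = 0} + theta * sum_N Pois(N | lam) *
    prod_j Binom(y_j | N, p_j)`` over ``N`` in the given range, accumulated
    in log space with successive terms from the closed-form N -> N+1 ratio.
    """
    y, m = _unwrap(counts, "counts")
    m = _as_mask(mask if m is None else m, y.shape)
    y = y[m].astype(int)
    p = np.broadcast_to(np.asarray(p, dtype=float), m.shape)[m].astype(float)
    if not (0.0 <= theta <= 1.0) or lam <= 0 or np.any((p < 0) | (p > 1)):
        raise ValueError("theta, p in [0,1] and lambda > 0 required")
    maxy = int(y.max()) if y.size else 0
    if nrange.nmin < maxy:
        raise ValueError(f"Nmin {nrange.nmin} below max observed count {maxy}")
    n0, n1 = nrange.nmin, nrange.nmax
    with np.errstate(divide="ignore", invalid="ignore"):
        # log a_{N0} = log Pois(N0 | lam) + sum_j log Binom(y_j | N0, p_j)
        la0 = (n0 * np.log(lam) - lam - gammaln(n0 + 1)
               + np.sum(gammaln(n0 + 1) - gammaln(y + 1) - gammaln(n0 - y + 1)
                        + xlogy(y, p) + xlog1py(n0 - y, -p)))
        if n1 > n0:
            ns = np.arange(n0 + 1, n1 + 1, dtype=float)  # step N-1 -> N
            inc = (np.log(lam) - np.log(ns)
                   + np.log1p(-p).sum() * 1.0
                   + y.size * np.log(ns)
                   - np.log(ns[:, None] - y[None, :]).sum(axis=1))
            la = np.concatenate(([la0], la0 + np.cumsum(inc)))
        else:
            la = np.array([la0])
        s = logsumexp(la)
        zero_branch = np.log1p(-theta) if maxy == 0 else NEG_INF
        occ_branch = (np.log(theta) + s) if theta > 0 else NEG_INF
    return float(np.logaddexp(zero_branch, occ_branch))
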