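"""MCMC efficiency diagnostics.

The benchmarking metric is *MCMC efficiency*: effective sample size divided
by sampling-loop computation time, summarized by its minimum across all
monitored parameters (the slowest-mixing parameter limits the validity of
every result).  ``1000 / efficiency`` converts efficiency into the waiting
time for 1,000 effectively independent samples of the worst parameter.

ESS uses the Geyer initial-monotone-positive-sequence truncation of the
autocovariance sum, which has a closed-form AR(1) oracle
(ESS/n -> (1 - rho)/(1 + rho)) and is cross-checked against an independent
library implementation in the test suite.  The Geweke convergence statistic
compares early and late window means with spectral-density-at-zero variance
estimates (same truncated-autocovariance estimator).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acovf

__all__ = ["ess", "geweke_z", "EfficiencyReport", "min_efficiency",
           "time_to_1000", "format_duration", "compare_posteriors"]


def _geyer_tau(x: np.ndarray) -> float:
    """Integrated autocorrelation time 1 + 2*sum(rho_k), Geyer-truncated."""
    n = x.size
    c = acovf(x, fft=True, demean=True)
    c0 = c[0]
    if c0 <= 0:
        return np.inf  # zero-variance chain
    # pair sums Gamma_k = rho_{2k} + rho_{2k+1}: initial positive, then
    # enforce monotone non-increase
    npair = (n - 1) // 2
    tau = -1.0  # accumulates 2*sum_{k>=0} Gamma_k - 1 form below
    run_min = np.inf
    total = 0.0
    for k in range(npair + 1):
        i, j = 2 * k, 2 * k + 1
        g = c[i] / c0 + (c[j] / c0 if j < n else 0.0)
        if g <= 0:
            break
        run_min = min(run_min, g)
        total += run_min
    tau = max(2.0 * total - 1.0, 1.0)
    return tau


def ess(chain) -> float:
    """Effective sample size of a scalar chain.

    ``n / (1 + 2 sum rho_k)`` with the autocovariance sum truncated by the
    initial-monotone-positive-sequence rule.  A zero-variance (constant)
    chain has ESS 0.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("ess needs a 1-D chain of length >= 10")
    if not np.all(np.isfinite(x)):
        raise ValueError("chain contains non-finite values")
    if np.ptp(x) == 0.0:
        return 0.0
    tau = _geyer_tau(x)
    if not np.isfinite(tau):
        return 0.0
    return float(min(x.size / tau, x.size))


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean with autocorrelation correction."""
    if np.ptp(x) == 0.0:
        return 0.0
    tau = _geyer_tau(x)
    return float(np.var(x, ddof=1) * tau / x.size)


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late window means."""
    x = np.asarray(chain, dtype=float)
    if not 0 < first < 1 or not 0 < last < 1 or first + last > 1:
        raise ValueError("windows must be fractions with first + last <= 1")
    n = x.size
    na, nb = int(n * first), int(n * last)
    if na < 10 or nb < 10:
        raise ValueError("chain too short for the requested windows")
    a, b = x[:na], x[n - nb:]
    va, vb = _spectral_var_of_mean(a), _spectral_var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def format_duration(seconds: float) -> str:
    """Humanize a duration the way efficiency conversions are usually quoted:
    days above one day, minutes above one minute, else seconds, one decimal.
    """
    def fmt(v):
        s = f"{v:.1f}"
        return s[:-2] if s.endswith(".0") else s

    if seconds >= 86400:
        return f"{fmt(seconds / 86400)} days"
    if seconds >= 60:
        return f"{fmt(seconds / 60)} min"
    return f"{fmt(seconds)} s"


def time_to_1000(efficiency: float) -> tuple[float, str]:
    """Seconds (and a humanized rendering) to reach 1,000 effective samples."""
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    secs = 1000.0 / efficiency
    return secs, format_duration(secs)


@dataclasses.dataclass
class EfficiencyReport:
    """Per-parameter ESS and efficiency with the min-efficiency summary."""

    ess: dict
    loop_seconds: float
    iterations: int
    burn_in: int
    efficiency: dict            # ESS per second
    efficiency_per_iter: dict   # ESS per post-burn-in iteration
    min_efficiency: float
    min_efficiency_per_iter: float
    argmin: str
    geweke: dict
    time_to_1000_s: float
    time_to_1000_str: str
    meta: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.ess):
            rows.append(dict(parameter=k, ess=self.ess[k],
                             efficiency=self.efficiency[k],
                             ess_per_iter=self.efficiency_per_iter[k],
                             geweke_z=self.geweke[k]))
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return dict(min_efficiency=self.min_efficiency,
                    min_ess_per_iter=self.min_efficiency_per_iter,
                    argmin=self.argmin, loop_seconds=self.loop_seconds,
                    iterations=self.iterations, burn_in=self.burn_in,
                    time_to_1000_s=self.time_to_1000_s,
                    time_to_1000=self.time_to_1000_str, **self.meta)


def min_efficiency(result, burn_in_fraction: float = 0.1) -> EfficiencyReport:
    """Efficiency report for a :class:`~hiermcmc.engine.ChainResult`.

    The timing denominator is the sampling-loop wall time only (model build
    and initialization are excluded upstream).  The stated burn-in fraction
    is removed before computing ESS.
    """
    if result.loop_seconds <= 0:
        raise ValueError("zero or negative sampling-loop runtime")
    burn = int(result.iterations * burn_in_fraction)
    kept = result.samples[burn:]
    niter = kept.shape[0]
    ess_d, eff_d, effit_d, gew_d = {}, {}, {}, {}
    for k, name in enumerate(result.columns):
        x = kept[:, k]
        e = ess(x)
        ess_d[name] = e
        eff_d[name] = e / result.loop_seconds
        effit_d[name] = e / niter
        gew_d[name] = geweke_z(x)
    # deterministic argmin: lexicographically smallest name among ties
    min_eff = min(eff_d.values())
    argmin = min(k for k, v in eff_d.items() if v == min_eff)
    secs, human = (time_to_1000(min_eff) if min_eff > 0
                   else (float("inf"), "unbounded"))
    return EfficiencyReport(
        ess=ess_d, loop_seconds=result.loop_seconds,
        iterations=result.iterations, burn_in=burn,
        efficiency=eff_d, efficiency_per_iter=effit_d,
        min_efficiency=min_eff,
        min_efficiency_per_iter=min(effit_d.values()),
        argmin=argmin, geweke=gew_d,
        time_to_1000_s=secs, time_to_1000_str=human,
        meta=dict(strategy=getattr(result, "strategy_id", None),
                  model=getattr(result, "model_desc", None),
                  seed=getattr(result, "seed", None)),
    )


def compare_posteriors(results, params=None, burn_in_fraction: float = 0.1,
                       threshold: float = 3.0) -> pd.DataFrame:
    """Pairwise posterior-agreement table across chains.

    For every shared monitored parameter and every pair of chains, reports
    the absolute difference in posterior means scaled by the pooled posterior
    sd, plus the two-sample Kolmogorov-Smirnov statistic; rows exceeding the
    pooled-sd threshold are flagged.
    """
    if len(results) < 2:
        raise ValueError("need at least two chains to compare")
    cols = set(results[0].columns)
    for r in results[1:]:
        cols &= set(r.columns)
    if params is not None:
        cols &= set(params)
    if not cols:
        raise ValueError("chains share no monitored parameters")
    rows = []
    for name in sorted(cols):
        draws = []
        for r in results:
            burn = int(r.iterations * burn_in_fraction)
            draws.append(r.samples[burn:, list(r.columns).index(name)])
        for a in range(len(draws)):
            for b in range(a + 1, len(draws)):
                xa, xb = draws[a], draws[b]
                pooled = np.sqrt(0.5 * (xa.var(ddof=1) + xb.var(ddof=1)))
                dmean = abs(xa.mean() - xb.mean())
                ratio = dmean / pooled if pooled > 0 else (0.0 if dmean == 0
                                                           else np.inf)
                ks = stats.ks_2samp(xa, xb)
                rows.append(dict(parameter=name, chain_a=a, chain_b=b,
                                 mean_diff=dmean, pooled_sd=pooled,
                                 sd_ratio=ratio, ks_stat=ks.statistic,
                                 flagged=bool(ratio > threshold)))
    return pd.DataFrame(rows)
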