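"""The compared sampler suite: five updater kinds with their adaptation rules.

Scalar samplers target one element of one parameter array; block samplers
target an ordered list of elements.  Every sampler works against a
:class:`~hiermcmc.model_core.ModelState`, so evaluating a candidate value
touches only the log-density terms that depend on the target.

Adaptation follows standard adaptive-MCMC practice: acceptance-rate targets
0.44 (scalar random walk) and 0.234 (block random walk), an adaptation window
of 200 steps, and a diminishing gain ``1 / adapt_count**0.8`` so tuning
settles as the chain lengthens.  Slice widths adapt toward twice the mean
absolute jump.  Support violations are rejected through the model's -inf
sentinel; no reflection or transformation is applied.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .model_core import (
    ModelInconsistencyError,
    ModelState,
    NumericalError,
    NEG_INF,
)

logger = logging.getLogger(__name__)

ADAPT_INTERVAL = 200
SCALAR_TARGET_RATE = 0.44
BLOCK_TARGET_RATE = 0.234
SLICE_MAX_STEPS = 100
SLICE_MAX_CONTRACTIONS = 1000

__all__ = [
    "ARWMHSampler",
    "SliceSampler",
    "DiscreteGibbsSampler",
    "DiscreteSliceSampler",
    "BlockRWSampler",
    "AFSSSampler",
    "ADAPT_INTERVAL",
]


class _ScalarBase:
    """Shared bookkeeping for scalar samplers (one (name, index) target)."""

    kind = "scalar"

    def __init__(self, name: str, idx: int = 0):
        self.name = name
        self.idx = int(idx)
        self.steps = 0
        self.adapt_count = 0
        self.window_steps = 0

    @property
    def target(self):
        return (self.name, self.idx)

    def _gain(self) -> float:
        return 1.0 / self.adapt_count ** 0.8

    def summary(self) -> dict:
        return {"kind": self.kind, "target": f"{self.name}[{self.idx}]",
                "steps": self.steps}


class ARWMHSampler(_ScalarBase):
    """Adaptive random-walk Metropolis-Hastings for a continuous scalar.

    Proposes from a normal centered on the current value; the adaptive part
    rescales the proposal standard deviation toward a 0.44 acceptance rate.
    """

    kind = "arwmh"

    def __init__(self, name, idx=0, scale=1.0, adapt=True,
                 target_rate=SCALAR_TARGET_RATE):
        super().__init__(name, idx)
        if scale <= 0:
            raise ValueError("proposal scale must be positive")
        self.scale = float(scale)
        self.adapt = adapt
        self.target_rate = target_rate
        self.window_accepts = 0
        self.total_accepts = 0

    def step(self, state: ModelState, rng: np.random.Generator) -> bool:
        x = state.get(self.name, self.idx)
        prop = state.propose([(self.name, self.idx,
                               x + self.scale * rng.standard_normal())])
        # accept with probability min(1, exp(delta)); draw even on -inf so the
        # random stream does not depend on the proposal's support status
        u = rng.random()
        accept = prop.delta >= 0 or (prop.delta > NEG_INF and math.log(u) < prop.delta)
        if accept:
            prop.accept()
            self.window_accepts += 1
            self.total_accepts += 1
        else:
            prop.reject()
        self.steps += 1
        self.window_steps += 1
        if self.adapt and self.window_steps >= ADAPT_INTERVAL:
            self.adapt_scale()
        return accept

    def adapt_scale(self):
        self.adapt_count += 1
        rate = self.window_accepts / max(self.window_steps, 1)
        self.scale *= math.exp(self._gain() * (rate - self.target_rate))
        self.window_accepts = 0
        self.window_steps = 0

    def summary(self):
        s = super().summary()
        s.update(scale=self.scale,
                 accept_rate=self.total_accepts / max(self.steps, 1))
        return s


class _SliceMixin:
    """Width bookkeeping shared by the continuous and discrete slice samplers."""

    def _init_width(self, width):
        if width <= 0:
            raise ValueError("slice width must be positive")
        self.width = float(width)
        self.jump_sum = 0.0
        self.jump_n = 0

    def _record_jump(self, jump, adapt=True):
        self.jump_sum += abs(jump)
        self.jump_n += 1
        self.steps += 1
        self.window_steps += 1
        if adapt and self.window_steps >= ADAPT_INTERVAL:
            self.adapt_count += 1
            if self.jump_n:
                mean_jump = self.jump_sum / self.jump_n
                if mean_jump > 0:
                    g = self._gain()
                    self.width += g * (2.0 * mean_jump - self.width)
            self.jump_sum = 0.0
            self.jump_n = 0
            self.window_steps = 0


def _conditional_delta(state, name, idx, x) -> float:
    prop = state.propose([(name, idx, x)])
    d = prop.delta
    prop.reject()
    return d


class SliceSampler(_ScalarBase, _SliceMixin):
    """Neal's stepping-out/shrinkage slice sampler for a continuous scalar.

    Assumes a unimodal conditional (the caller's responsibility); always
    returns a point whose conditional log density is at or above the slice
    level, so it almost always moves.
    """

    kind = "slice"

    def __init__(self, name, idx=0, width=1.0, adapt=True):
        super().__init__(name, idx)
        self._init_width(width)
        self.adapt = adapt

    def step(self, state: ModelState, rng: np.random.Generator):
        name, idx = self.name, self.idx
        x0 = state.get(name, idx)
        level = -rng.exponential()  # log f(x) - log f(x0) scale: current is 0
        w = self.width
        L = x0 - w * rng.random()
        R = L + w
        k = SLICE_MAX_STEPS
        while k > 0 and _conditional_delta(state, name, idx, L) > level:
            L -= w
            k -= 1
        k = SLICE_MAX_STEPS
        while k > 0 and _conditional_delta(state, name, idx, R) > level:
            R += w
            k -= 1
        for _ in range(SLICE_MAX_CONTRACTIONS):
            x1 = rng.uniform(L, R)
            prop = state.propose([(name, idx, x1)])
            if prop.delta >= level:
                prop.accept()
                self._record_jump(x1 - x0, self.adapt)
                return x1
            prop.reject()
            if x1 < x0:
                L = x1
            else:
                R = x1
        raise NumericalError(
            f"slice sampler for {name}[{idx}] exceeded "
            f"{SLICE_MAX_CONTRACTIONS} contractions (level={level:.3g}, "
            f"x0={x0:.6g}, window=[{L:.6g}, {R:.6g}])"
        )


class DiscreteGibbsSampler(_ScalarBase):
    """Computational Gibbs: enumerate every support value of a discrete
    parameter, normalize the conditional by direct computation, sample exactly.
    """

    kind = "discrete_gibbs"

    def __init__(self, name, idx=0, values=None):
        super().__init__(name, idx)
        self._values = None if values is None else np.asarray(values, dtype=float)

    def _support_values(self, state):
        if self._values is not None:
            return self._values
        vals = state.model.param_map[self.name].support.enumerate()
        if vals is None:
            raise ModelInconsistencyError(
                f"{self.name!r} has non-enumerable support; computational "
                "Gibbs needs a finite value set"
            )
        return vals

    def step(self, state: ModelState, rng: np.random.Generator):
        name, idx = self.name, self.idx
        current = state.get(name, idx)
        vals = self._support_values(state)
        tids = state.model.affected_terms(name, idx)
        cur_delta = 0.0 if np.all(np.isfinite(state.term_vals[tids])) else NEG_INF
        deltas = np.empty(len(vals))
        for k, v in enumerate(vals):
            deltas[k] = (cur_delta if v == current
                         else _conditional_delta(state, name, idx, v))
        if np.all(deltas == NEG_INF):
            raise ModelInconsistencyError(
                f"all support values of {name}[{idx}] have zero probability"
            )
        m = deltas.max()
        w = np.exp(deltas - m)
        probs = w / w.sum()
        choice = vals[rng.choice(len(vals), p=probs)]
        if choice != current:
            prop = state.propose([(name, idx, choice)])
            prop.accept()
        self.steps += 1
        return choice


class DiscreteSliceSampler(_ScalarBase, _SliceMixin):
    """Slice sampler on the integer lattice for unbounded discrete parameters
    (latent Poisson abundances).  Stepping-out and shrinkage run over integer
    candidates; the returned value always satisfies the slice condition.
    """

    kind = "discrete_slice"

    def __init__(self, name, idx=0, width=2.0, adapt=True, lower=0):
        super().__init__(name, idx)
        self._init_width(width)
        self.adapt = adapt
        self.lower = lower

    def step(self, state: ModelState, rng: np.random.Generator):
        name, idx = self.name, self.idx
        x0 = int(state.get(name, idx))
        level = -rng.exponential()
        w = max(1, int(round(self.width)))
        L = x0 - int(rng.integers(0, w + 1))
        R = L + w
        L = max(L, self.lower)
        k = SLICE_MAX_STEPS
        while (k > 0 and L > self.lower
               and _conditional_delta(state, name, idx, L) > level):
            L = max(L - w, self.lower)
            k -= 1
        k = SLICE_MAX_STEPS
        while k > 0 and _conditional_delta(state, name, idx, R) > level:
            R += w
            k -= 1
        for _ in range(SLICE_MAX_CONTRACTIONS):
            x1 = int(rng.integers(L, R + 1))
            if x1 == x0:
                self._record_jump(0, self.adapt)
                return x0
            prop = state.propose([(name, idx, float(x1))])
            if prop.delta >= level:
                prop.accept()
                self._record_jump(x1 - x0, self.adapt)
                return x1
            prop.reject()
            if x1 < x0:
                L = x1 + 1
            else:
                R = x1 - 1
        raise NumericalError(
            f"discrete slice sampler for {name}[{idx}] exceeded "
            f"{SLICE_MAX_CONTRACTIONS} contractions"
        )


class _BlockBase:
    """Shared state for block samplers: targets, empirical moment accumulators."""

    kind = "block"

    def __init__(self, targets):
        self.targets = [(n, int(i)) for n, i in targets]
        if len(self.targets) < 1:
            raise ValueError("block sampler needs at least one target")
        self.d = len(self.targets)
        self.steps = 0
        self.adapt_count = 0
        self.window_steps = 0
        # running first/second moments of the retained chain
        self._n = 0
        self._mean = np.zeros(self.d)
        self._m2 = np.zeros((self.d, self.d))

    def _gain(self):
        return 1.0 / self.adapt_count ** 0.8

    def _x(self, state) -> np.ndarray:
        return np.array([state.get(n, i) for n, i in self.targets])

    def _accumulate(self, x):
        self._n += 1
        dlt = x - self._mean
        self._mean += dlt / self._n
        self._m2 += np.outer(dlt, x - self._mean)

    def empirical_cov(self) -> np.ndarray | None:
        if self._n < max(10, self.d + 2):
            return None
        return self._m2 / (self._n - 1)

    def summary(self):
        return {"kind": self.kind, "steps": self.steps,
                "targets": [f"{n}[{i}]" for n, i in self.targets]}


class BlockRWSampler(_BlockBase):
    """Adaptive multivariate random-walk Metropolis-Hastings.

    Joint proposal ``x' = x + s * L @ eps`` with ``L L^T`` the proposal
    covariance.  Adaptation tunes the global scale toward a 0.234 acceptance
    rate and replaces the proposal covariance with the (regularized)
    empirical covariance of the retained samples.
    """

    kind = "block_rw"

    COV_UPDATE_INTERVAL = 200
    COV_MIN_SAMPLES = 1000

    def __init__(self, targets, cov=None, scale=None, adapt=True,
                 target_rate=BLOCK_TARGET_RATE):
        super().__init__(targets)
        self.cov = np.eye(self.d) if cov is None else np.array(cov, dtype=float)
        self._chol = np.linalg.cholesky(self.cov)
        self.scale = float(scale) if scale is not None else 2.38 / math.sqrt(self.d)
        self.adapt = adapt
        self.target_rate = target_rate
        self.window_accepts = 0
        self.total_accepts = 0

    def step(self, state: ModelState, rng: np.random.Generator) -> bool:
        x = self._x(state)
        dx = self.scale * (self._chol @ rng.standard_normal(self.d))
        prop = state.propose(
            [(n, i, x[k] + dx[k]) for k, (n, i) in enumerate(self.targets)]
        )
        u = rng.random()
        accept = prop.delta >= 0 or (prop.delta > NEG_INF and math.log(u) < prop.delta)
        if accept:
            prop.accept()
            self.window_accepts += 1
            self.total_accepts += 1
            x = x + dx
        else:
            prop.reject()
        self._accumulate(x)
        self.steps += 1
        self.window_steps += 1
        if self.adapt and self.window_steps >= ADAPT_INTERVAL:
            self._adapt()
        return accept

    def _adapt(self):
        self.adapt_count += 1
        rate = self.window_accepts / max(self.window_steps, 1)
        self.scale *= math.exp(self._gain() * (rate - self.target_rate))
        self.window_accepts = 0
        self.window_steps = 0
        if self._n >= self.COV_MIN_SAMPLES:
            cov = self.empirical_cov()
            if cov is not None:
                cov = cov + 1e-8 * np.eye(self.d)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    logger.warning(
                        "block_rw proposal covariance lost positive "
                        "definiteness; resetting to scaled identity"
                    )
                    cov = np.eye(self.d) * np.maximum(np.diag(cov).mean(), 1e-8)
                    chol = np.linalg.cholesky(cov)
                self.cov, self._chol = cov, chol

    def summary(self):
        s = super().summary()
        s.update(scale=self.scale,
                 accept_rate=self.total_accepts / max(self.steps, 1))
        return s


class AFSSSampler(_BlockBase):
    """Automated-factor slice sampler.

    Univariate slice samplers applied along a set of orthogonal directions
    (the eigenvectors of the accumulated empirical posterior covariance),
    with per-direction widths.  Factors are recomputed every
    ``refactor_interval`` steps until ``freeze_after`` steps, then frozen;
    the adaptation must terminate because each factor update changes the
    coordinates being sliced.
    """

    kind = "block_afss"

    def __init__(self, targets, widths=None, refactor_interval=1000,
                 freeze_after=25000, adapt=True):
        super().__init__(targets)
        self.factors = np.eye(self.d)  # columns are directions
        self.widths = (np.full(self.d, 1.0) if widths is None
                       else np.array(widths, dtype=float))
        self.refactor_interval = refactor_interval
        self.freeze_after = freeze_after
        self.adapt = adapt
        self._jump_sum = np.zeros(self.d)
        self._jump_n = np.zeros(self.d)

    def _directional_delta(self, state, x, f, t) -> float:
        prop = state.propose(
            [(n, i, x[k] + t * f[k]) for k, (n, i) in enumerate(self.targets)]
        )
        d = prop.delta
        prop.reject()
        return d

    def _slice_along(self, state, rng, k) -> float:
        x = self._x(state)
        f = self.factors[:, k]
        w = self.widths[k]
        level = -rng.exponential()
        L = -w * rng.random()
        R = L + w
        n = SLICE_MAX_STEPS
        while n > 0 and self._directional_delta(state, x, f, L) > level:
            L -= w
            n -= 1
        n = SLICE_MAX_STEPS
        while n > 0 and self._directional_delta(state, x, f, R) > level:
            R += w
            n -= 1
        for _ in range(SLICE_MAX_CONTRACTIONS):
            t = rng.uniform(L, R)
            prop = state.propose(
                [(nm, i, x[j] + t * f[j]) for j, (nm, i) in enumerate(self.targets)]
            )
            if prop.delta >= level:
                prop.accept()
                return t
            prop.reject()
            if t < 0:
                L = t
            else:
                R = t
        raise NumericalError("AFSS slice exceeded contraction budget")

    def step(self, state: ModelState, rng: np.random.Generator):
        for k in range(self.d):
            t = self._slice_along(state, rng, k)
            self._jump_sum[k] += abs(t)
            self._jump_n[k] += 1
        self._accumulate(self._x(state))
        self.steps += 1
        self.window_steps += 1
        if not self.adapt:
            return
        if self.window_steps >= ADAPT_INTERVAL:
            self.adapt_count += 1
            g = self._gain()
            live = self._jump_n > 0
            mean_jump = np.where(live, self._jump_sum / np.maximum(self._jump_n, 1), 0)
            upd = live & (mean_jump > 0)
            self.widths[upd] += g * (2.0 * mean_jump[upd] - self.widths[upd])
            self._jump_sum[:] = 0
            self._jump_n[:] = 0
            self.window_steps = 0
        if (self.steps <= self.freeze_after
                and self.steps % self.refactor_interval == 0):
            self._refactor()

    def _refactor(self):
        cov = self.empirical_cov()
        if cov is None:
            return
        try:
            vals, vecs = np.linalg.eigh(cov)
        except np.linalg.LinAlgError:
            logger.warning("AFSS covariance eigendecomposition failed; "
                           "keeping previous factors")
            return
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            logger.warning("AFSS covariance degenerate; keeping previous factors")
            return
        order = np.argsort(vals)[::-1]
        self.factors = vecs[:, order]
        self.widths = 2.0 * np.sqrt(vals[order])

    def summary(self):
        s = super().summary()
        s.update(widths=self.widths.tolist())
        return s
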