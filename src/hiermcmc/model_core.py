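"""Generic representation of a Bayesian hierarchical model.

A model is a collection of named parameter arrays (:class:`ParamSpec`), a sum
of log-density terms (:class:`LogDensityTerm`) and an explicit dependency map
from parameters to the terms whose value they affect.  Samplers update one
scalar element (or one block of elements) at a time and recompute only the
affected terms, which is what makes single-site latent-state updates cheap
relative to full posterior re-evaluation.

Two access styles are provided:

* the pure functions :func:`log_posterior` and :func:`delta_log_posterior`,
  which operate on plain ``name -> array`` value maps, and
* :class:`ModelState`, a mutable chain state that caches per-term values so a
  proposal touches each affected term exactly once.

``-inf`` is the single sentinel for impossible states (support violations,
structural zeros).  A term returning NaN is treated as a defect and raises
:class:`NumericalError` rather than being silently rejected.
"""

from __future__ import annotations

import dataclasses
import math
from collections import namedtuple
from collections.abc import Callable, Mapping, Sequence

import numpy as np

NEG_INF = float("-inf")

__all__ = [
    "ConfigurationError",
    "NumericalError",
    "ModelInconsistencyError",
    "InitializationError",
    "Support",
    "PriorSpec",
    "ParamSpec",
    "LogDensityTerm",
    "HierModel",
    "ModelState",
    "DeltaResult",
    "log_posterior",
    "delta_log_posterior",
]


class ConfigurationError(Exception):
    """A structural problem with a model, plan or value map (not a -inf state)."""


class NumericalError(Exception):
    """A term produced NaN, or an iterative sampler exhausted its budget."""


class ModelInconsistencyError(Exception):
    """Every value of a discrete full conditional has zero probability."""


class InitializationError(Exception):
    """No finite-posterior initial state could be found."""


# ---------------------------------------------------------------------------
# supports


@dataclasses.dataclass(frozen=True)
class Support:
    """Domain of a parameter; values outside yield log density -inf."""

    kind: str  # real | positive | unit_interval | interval | nonneg_integer | binary
    lo: float = -math.inf
    hi: float = math.inf

    @classmethod
    def real(cls) -> "Support":
        return cls("real")

    @classmethod
    def positive(cls) -> "Support":
        return cls("positive", lo=0.0)

    @classmethod
    def unit_interval(cls) -> "Support":
        return cls("unit_interval", lo=0.0, hi=1.0)

    @classmethod
    def interval(cls, lo: float, hi: float) -> "Support":
        if not hi > lo:
            raise ConfigurationError(f"empty interval ({lo}, {hi})")
        return cls("interval", lo=lo, hi=hi)

    @classmethod
    def nonneg_integer(cls) -> "Support":
        return cls("nonneg_integer", lo=0.0)

    @classmethod
    def binary(cls) -> "Support":
        return cls("binary", lo=0.0, hi=1.0)

    @property
    def is_discrete(self) -> bool:
        return self.kind in ("nonneg_integer", "binary")

    def contains(self, x) -> bool:
        x = np.asarray(x)
        if not np.all(np.isfinite(x)):
            return False
        if self.kind == "real":
            return True
        if self.kind == "positive":
            return bool(np.all(x > 0))
        if self.kind in ("unit_interval", "interval"):
            return bool(np.all((x >= self.lo) & (x <= self.hi)))
        if self.kind == "nonneg_integer":
            return bool(np.all((x >= 0) & (x == np.floor(x))))
        if self.kind == "binary":
            return bool(np.all((x == 0) | (x == 1)))
        raise ConfigurationError(f"unknown support kind {self.kind!r}")

    def enumerate(self) -> np.ndarray | None:
        """Finite support values, or None if the support is infinite."""
        if self.kind == "binary":
            return np.array([0.0, 1.0])
        return None


# ---------------------------------------------------------------------------
# parameters and priors


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Distribution descriptor: family plus hyperparameters.

    Hyperparameter values may be constants or strings naming another model
    parameter (a reference, used for random effects drawn from common
    distributions with sampled hyperparameters).
    """

    family: str  # normal | uniform
    params: tuple  # (("mean", 0.0), ("sd", 100.0)) style for hashability

    @classmethod
    def normal(cls, mean=0.0, sd=1.0) -> "PriorSpec":
        return cls("normal", (("mean", mean), ("sd", sd)))

    @classmethod
    def uniform(cls, lo=0.0, hi=1.0) -> "PriorSpec":
        return cls("uniform", (("lo", lo), ("hi", hi)))

    def param(self, key):
        for k, v in self.params:
            if k == key:
                return v
        raise KeyError(key)

    def resolve(self, key, values: Mapping) -> float:
        v = self.param(key)
        if isinstance(v, str):
            return float(np.asarray(values[v]).reshape(()))
        return float(v)


@dataclasses.dataclass(frozen=True)
class ParamSpec:
    """One named parameter array of the model.

    role: "top" for top-level parameters (the ones counted in model-size
    summaries and monitored by default), "random" for continuous unit-specific
    random effects drawn from common distributions, "latent" for discrete
    latent states (binary occupancy, non-negative integer abundance).
    """

    name: str
    shape: tuple = ()
    support: Support = Support.real()
    prior: PriorSpec | None = None
    role: str = "top"

    def __post_init__(self):
        if self.role not in ("top", "random", "latent"):
            raise ConfigurationError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "latent" and not self.support.is_discrete:
            raise ConfigurationError(
                f"latent parameter {self.name!r} must have discrete support"
            )

    @property
    def size(self) -> int:
        return int(np.prod(self.shape, dtype=int)) if self.shape else 1


@dataclasses.dataclass
class LogDensityTerm:
    """One additive contribution to the log posterior.

    ``inputs`` lists exactly the parameters whose change alters the term.  If
    a parameter name also appears in ``indexed_inputs``, the dependence is
    restricted to the listed flat element indices of that parameter (used for
    per-site latent states inside vector parameters).
    """

    name: str
    inputs: tuple
    eval: Callable[[Mapping], float]
    indexed_inputs: dict | None = None  # name -> iterable of flat indices
    data_slice: str | None = None


DeltaResult = namedtuple("DeltaResult", ["value", "absolute"])


# ---------------------------------------------------------------------------
# model


class HierModel:
    """Parameters + log-density terms + dependency map."""

    def __init__(
        self,
        params: Sequence[ParamSpec],
        terms: Sequence[LogDensityTerm],
        data=None,
        monitors: Sequence[str] | None = None,
        block_groups: Sequence[Sequence[tuple]] | None = None,
        meta: dict | None = None,
        declared_top_level: int | None = None,
    ):
        self.params = list(params)
        self.terms = list(terms)
        self.data = data
        self.meta = dict(meta or {})
        self.block_groups = [list(g) for g in block_groups] if block_groups else None
        self.declared_top_level = declared_top_level
        self.param_map = {}
        for p in self.params:
            if p.name in self.param_map:
                raise ConfigurationError(f"duplicate parameter name {p.name!r}")
            self.param_map[p.name] = p
        names = set(self.param_map)
        tnames = set()
        for t in self.terms:
            if t.name in tnames:
                raise ConfigurationError(f"duplicate term name {t.name!r}")
            tnames.add(t.name)
            unknown = set(t.inputs) - names
            if unknown:
                raise ConfigurationError(f"term {t.name!r} references {unknown}")
            if t.indexed_inputs:
                extra = set(t.indexed_inputs) - set(t.inputs)
                if extra:
                    raise ConfigurationError(
                        f"term {t.name!r}: indexed_inputs {extra} not in inputs"
                    )
        self.monitors = list(monitors) if monitors is not None else [
            p.name for p in self.params if p.role == "top"
        ]
        for m in self.monitors:
            if m not in self.param_map:
                raise ConfigurationError(f"unknown monitor {m!r}")
        if self.declared_top_level is not None:
            n = self.top_level_count()
            if n != self.declared_top_level:
                raise ConfigurationError(
                    f"declared {self.declared_top_level} top-level scalars, built {n}"
                )
        self._build_dependency_index()
        self.eval_count = 0

    # -- dependency bookkeeping -------------------------------------------

    def _build_dependency_index(self):
        self._full_dep = {p.name: [] for p in self.params}
        self._elem_dep = {p.name: {} for p in self.params}
        for tid, t in enumerate(self.terms):
            idx = t.indexed_inputs or {}
            for name in t.inputs:
                if name in idx:
                    for k in np.atleast_1d(np.asarray(idx[name], dtype=int)):
                        self._elem_dep[name].setdefault(int(k), []).append(tid)
                else:
                    self._full_dep[name].append(tid)
        # freeze into arrays, and cache combined (full + elementwise) lookups
        self._affected_cache = {}

    def affected_terms(self, name: str, idx: int | None = None) -> list:
        """Term ids whose value can change when element ``idx`` of ``name`` moves."""
        if name not in self.param_map:
            raise ConfigurationError(f"unknown parameter {name!r}")
        key = (name, idx)
        got = self._affected_cache.get(key)
        if got is not None:
            return got
        tids = list(self._full_dep[name])
        if idx is None:
            seen = set(tids)
            for lst in self._elem_dep[name].values():
                for t in lst:
                    if t not in seen:
                        seen.add(t)
                        tids.append(t)
        else:
            tids = tids + self._elem_dep[name].get(int(idx), [])
        self._affected_cache[key] = tids
        return tids

    @property
    def dep_map(self) -> dict:
        """Parameter name -> set of term names (inverse of the inputs lists)."""
        return {
            p.name: {self.terms[t].name for t in self.affected_terms(p.name)}
            for p in self.params
        }

    # -- evaluation --------------------------------------------------------

    def eval_term(self, tid: int, values: Mapping) -> float:
        self.eval_count += 1
        v = float(self.terms[tid].eval(values))
        if math.isnan(v):
            raise NumericalError(f"term {self.terms[tid].name!r} returned NaN")
        return v

    def reset_eval_count(self):
        self.eval_count = 0

    # -- conveniences ------------------------------------------------------

    def top_level_count(self) -> int:
        return sum(p.size for p in self.params if p.role == "top")

    def latent_count(self) -> int:
        return sum(p.size for p in self.params if p.role == "latent")

    def validate_values(self, values: Mapping):
        for p in self.params:
            if p.name not in values:
                raise ConfigurationError(f"missing value for parameter {p.name!r}")
            arr = np.asarray(values[p.name], dtype=float)
            if arr.shape != tuple(p.shape):
                raise ConfigurationError(
                    f"{p.name!r}: value shape {arr.shape} != spec shape {tuple(p.shape)}"
                )

    def pack_values(self, values: Mapping) -> dict:
        """Copy a value map into float arrays with the spec shapes."""
        self.validate_values(values)
        return {
            p.name: np.array(values[p.name], dtype=float).reshape(p.shape)
            for p in self.params
        }


# ---------------------------------------------------------------------------
# functional interface


def log_posterior(model: HierModel, values: Mapping) -> float:
    """Sum of all log-density terms; -inf propagates, never NaN."""
    model.validate_values(values)
    for p in model.params:
        if not p.support.contains(values[p.name]):
            return NEG_INF
    total = 0.0
    for tid in range(len(model.terms)):
        v = model.eval_term(tid, values)
        if v == NEG_INF:
            return NEG_INF
        total += v
    return total


def _parse_changed(changed):
    if isinstance(changed, tuple):
        return changed[0], (None if changed[1] is None else int(changed[1]))
    return changed, None


def delta_log_posterior(model: HierModel, values: Mapping, changed, new_value) -> DeltaResult:
    """Change in log posterior from updating one parameter (element).

    Only the terms listed in the dependency map for the changed parameter are
    re-evaluated.  If the old affected-term sum is -inf (so the difference is
    ill-defined), the full new-state log posterior is returned with
    ``absolute=True``.
    """
    name, idx = _parse_changed(changed)
    if name not in model.param_map:
        raise ConfigurationError(f"unknown parameter {name!r}")
    model.validate_values(values)
    spec = model.param_map[name]
    tids = model.affected_terms(name, idx)
    old_sum = 0.0
    for t in tids:
        old_sum += model.eval_term(t, values)

    new_values = dict(values)
    arr = np.array(values[name], dtype=float).reshape(spec.shape)
    if idx is None:
        arr = np.array(new_value, dtype=float).reshape(spec.shape)
    else:
        arr.flat[idx] = new_value
    new_values[name] = arr

    if not spec.support.contains(arr):
        return DeltaResult(NEG_INF, False)
    if old_sum == NEG_INF:
        return DeltaResult(log_posterior(model, new_values), True)
    new_sum = 0.0
    for t in tids:
        v = model.eval_term(t, new_values)
        if v == NEG_INF:
            return DeltaResult(NEG_INF, False)
        new_sum += v
    return DeltaResult(new_sum - old_sum, False)


# ---------------------------------------------------------------------------
# cached chain state


class _Proposal:
    __slots__ = ("state", "delta", "_updates", "_old_elems", "_tids", "_old_tvals",
                 "_new_tvals", "_applied", "_open")

    def __init__(self, state, delta, updates, old_elems, tids, old_tvals,
                 new_tvals, applied):
        self.state = state
        self.delta = delta
        self._updates = updates
        self._old_elems = old_elems
        self._tids = tids
        self._old_tvals = old_tvals
        self._new_tvals = new_tvals
        self._applied = applied
        self._open = True

    def accept(self):
        if not self._open:
            raise RuntimeError("proposal already resolved")
        if not self._applied or self.delta == NEG_INF:
            raise RuntimeError("cannot accept an impossible proposal")
        st = self.state
        for t, v in zip(self._tids, self._new_tvals):
            st.term_vals[t] = v
        st.logp += self.delta
        self._open = False

    def reject(self):
        if not self._open:
            raise RuntimeError("proposal already resolved")
        if self._applied:
            st = self.state
            for (name, idx, _), old in zip(self._updates, self._old_elems):
                st.values[name].flat[idx] = old
        self._open = False


class ModelState:
    """Mutable chain state with cached per-term values.

    The chain invariant is that the total log posterior is finite, hence every
    cached term value is finite; delta computations therefore never hit the
    -inf minus -inf case.
    """

    def __init__(self, model: HierModel, values: Mapping):
        self.model = model
        self.values = model.pack_values(values)
        for p in model.params:
            if not p.support.contains(self.values[p.name]):
                raise InitializationError(f"initial {p.name!r} outside support")
        self.term_vals = np.empty(len(model.terms))
        for tid in range(len(model.terms)):
            self.term_vals[tid] = model.eval_term(tid, self.values)
        self.logp = float(self.term_vals.sum())

    def get(self, name: str, idx: int = 0) -> float:
        return float(self.values[name].flat[idx])

    def propose(self, updates: Sequence[tuple]) -> _Proposal:
        """Stage scalar-element updates ``[(name, flat_idx, new_value), ...]``.

        Returns a proposal whose ``delta`` is the change in log posterior.
        Exactly one of ``accept()`` / ``reject()`` must then be called.  A
        support-violating proposal is never applied and has delta -inf.
        """
        model = self.model
        for name, idx, newv in updates:
            spec = model.param_map[name]
            if not spec.support.contains(newv):
                return _Proposal(self, NEG_INF, updates, (), (), (), (), False)
        # union of affected terms, preserving first-seen order
        if len(updates) == 1:
            name, idx, _ = updates[0]
            tids = model.affected_terms(name, idx)
        else:
            tids = []
            seen = set()
            for name, idx, _ in updates:
                for t in model.affected_terms(name, idx):
                    if t not in seen:
                        seen.add(t)
                        tids.append(t)
        old_elems = [self.values[name].flat[idx] for name, idx, _ in updates]
        for name, idx, newv in updates:
            self.values[name].flat[idx] = newv
        old_sum = 0.0
        for t in tids:
            old_sum += self.term_vals[t]
        new_tvals = []
        new_sum = 0.0
        for t in tids:
            v = model.eval_term(t, self.values)
            new_tvals.append(v)
            if v == NEG_INF:
                new_sum = NEG_INF
                break
            new_sum += v
        delta = NEG_INF if new_sum == NEG_INF else new_sum - old_sum
        return _Proposal(self, delta, updates, old_elems, tids[: len(new_tvals)],
                         None, new_tvals, True)

    def recompute(self):
        """Full re-evaluation (defensive; used by tests and after init)."""
        for tid in range(len(self.model.terms)):
            self.term_vals[tid] = self.model.eval_term(tid, self.values)
        self.logp = float(self.term_vals.sum())
        return self.logp
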