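"""Sampler-assignment strategies: map a model to an ordered SamplerPlan.

Two default-assignment schemes are provided, mirroring the two software
conventions being compared:

* ``nimble_default`` — adaptive random-walk Metropolis-Hastings for every
  continuous scalar, computational Gibbs for binary/categorical latents, and
  an integer slice sampler for unbounded discrete latents;
* ``jags_like`` — a slice sampler for every continuous scalar, computational
  Gibbs for finite-support discrete parameters, integer slice for
  infinite-support discrete parameters.

The two blocking strategies (``block_rw``, ``block_afss``) layer a block
sampler over the model's declared block groups and fall back to the
``nimble_default`` rules for everything else.  Block groups follow the
per-model blocking choices: year-wise (persistence, colonization) pairs for
the single-species multiseason model, one slopes+intercept block per species
for the multispecies models, and a single intercept+slopes block for the
N-mixture abundance predictor.
"""

from __future__ import annotations

import dataclasses

from .model_core import ConfigurationError, HierModel
from . import samplers as S

STRATEGIES = ("nimble_default", "jags_like", "block_rw", "block_afss")

__all__ = ["PlanEntry", "SamplerPlan", "assign_samplers", "make_blocking_plan",
           "build_samplers", "STRATEGIES"]


@dataclasses.dataclass(frozen=True)
class PlanEntry:
    kind: str  # arwmh | slice | discrete_gibbs | discrete_slice | block_rw | block_afss
    targets: tuple  # ((name, flat_idx), ...)


@dataclasses.dataclass(frozen=True)
class SamplerPlan:
    entries: tuple
    strategy_id: str

    def covered_targets(self):
        out = []
        for e in self.entries:
            out.extend(e.targets)
        return out

    def describe(self) -> str:
        lines = [f"strategy: {self.strategy_id} ({len(self.entries)} entries)"]
        for e in self.entries:
            tgt = ", ".join(f"{n}[{i}]" for n, i in e.targets)
            lines.append(f"  {e.kind}: {tgt}")
        return "\n".join(lines)


def _scalar_kind(spec, strategy_id: str) -> str:
    if spec.support.is_discrete:
        finite = spec.support.enumerate() is not None
        if strategy_id == "jags_like":
            return "discrete_gibbs" if finite else "discrete_slice"
        # nimble-style: computational Gibbs for binary/categorical,
        # slice for unbounded discrete
        return "discrete_gibbs" if finite else "discrete_slice"
    return "slice" if strategy_id == "jags_like" else "arwmh"


def assign_samplers(model: HierModel, strategy_id: str) -> SamplerPlan:
    """Produce the ordered sampler plan for one strategy.

    Every sampled parameter element is covered by exactly one entry;
    marginalized models (no latent-role parameters) yield no latent entries.
    """
    if strategy_id not in STRATEGIES:
        raise ConfigurationError(
            f"unknown strategy {strategy_id!r}; choose from {STRATEGIES}"
        )
    blocked = set()
    entries = []
    if strategy_id in ("block_rw", "block_afss"):
        groups = make_blocking_plan(model.meta.get("model_kind"), model)
        for g in groups:
            entries.append(PlanEntry(strategy_id, tuple((n, int(i)) for n, i in g)))
            blocked.update((n, int(i)) for n, i in g)
    base = "jags_like" if strategy_id == "jags_like" else "nimble_default"
    for spec in model.params:
        kind = _scalar_kind(spec, base)
        for i in range(spec.size):
            if (spec.name, i) in blocked:
                continue
            entries.append(PlanEntry(kind, ((spec.name, i),)))
    plan = SamplerPlan(tuple(entries), strategy_id)
    _audit_coverage(model, plan)
    return plan


def _audit_coverage(model: HierModel, plan: SamplerPlan):
    need = {(p.name, i) for p in model.params for i in range(p.size)}
    got = plan.covered_targets()
    gotset = set(got)
    if len(got) != len(gotset):
        raise ConfigurationError("plan covers some parameter more than once")
    if gotset != need:
        raise ConfigurationError(
            f"plan coverage mismatch: missing {need - gotset}, extra {gotset - need}"
        )


def make_blocking_plan(model_kind, model: HierModel):
    """Block groups for a builder-produced model.

    Groups are declared by the model builders (they know the coefficient
    layout); this validates their presence and shape.
    """
    if model.block_groups is None:
        raise ConfigurationError(
            f"model {model_kind!r} declares no block groups; blocking "
            "strategies require them"
        )
    groups = [list(g) for g in model.block_groups]
    for g in groups:
        if len(g) < 2:
            raise ConfigurationError("block groups must have at least 2 elements")
        for n, i in g:
            if n not in model.param_map:
                raise ConfigurationError(f"block group references unknown {n!r}")
            if not 0 <= int(i) < model.param_map[n].size:
                raise ConfigurationError(f"block index {i} out of range for {n!r}")
    return groups


def build_samplers(model: HierModel, plan: SamplerPlan, init_scales=None):
    """Instantiate stateful sampler objects for a plan, in plan order."""
    out = []
    for e in plan.entries:
        if e.kind == "arwmh":
            (name, idx), = e.targets
            out.append(S.ARWMHSampler(name, idx))
        elif e.kind == "slice":
            (name, idx), = e.targets
            out.append(S.SliceSampler(name, idx))
        elif e.kind == "discrete_gibbs":
            (name, idx), = e.targets
            out.append(S.DiscreteGibbsSampler(name, idx))
        elif e.kind == "discrete_slice":
            (name, idx), = e.targets
            out.append(S.DiscreteSliceSampler(name, idx))
        elif e.kind == "block_rw":
            out.append(S.BlockRWSampler(list(e.targets)))
        elif e.kind == "block_afss":
            out.append(S.AFSSSampler(list(e.targets)))
        else:
            raise ConfigurationError(f"unknown sampler kind {e.kind!r}")
    return out
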