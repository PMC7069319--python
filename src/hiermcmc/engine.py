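"""MCMC driver: execute a sampler plan over a model and benchmark cells.

``run_mcmc`` performs one full sweep of the plan's sampler entries per
iteration, in plan order, records every monitored scalar every iteration
(no thinning), and times the sampling loop only — model construction,
initialization and adaptation bookkeeping inside samplers are part of the
loop, but building the model and drawing initial values are not, since they
are one-off preparation costs rather than properties of the algorithm.

``run_benchmark`` executes a factorial set of (model variant, strategy)
cells and collects one efficiency report per cell, with relative-efficiency
ratios against a named baseline cell.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np
import pandas as pd

from .case_models import ModelConfig, build_model
from .diagnostics import EfficiencyReport, min_efficiency
from .model_core import (
    HierModel,
    InitializationError,
    ModelState,
    NEG_INF,
)
from .simulate import simulate_for
from .strategies import SamplerPlan, assign_samplers, build_samplers

logger = logging.getLogger(__name__)

__all__ = ["ChainResult", "run_mcmc", "draw_initial_values", "BenchmarkCell",
           "run_benchmark"]


@dataclasses.dataclass
class ChainResult:
    """Posterior draws (iterations x monitored scalars) plus run metadata."""

    samples: np.ndarray
    columns: tuple
    loop_seconds: float
    iterations: int
    seed: int
    strategy_id: str
    model_desc: dict
    sampler_summaries: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.columns))


def _initial_from_prior(spec, rng):
    pr = spec.prior
    if pr is None:
        return np.zeros(spec.shape)
    if pr.family == "uniform":
        lo, hi = pr.param("lo"), pr.param("hi")
        if hi - lo >= 10.0:
            # near-flat sd hyperpriors make poor starts; begin at 1
            return np.full(spec.shape, 1.0)
        return rng.uniform(lo, hi, size=spec.shape)
    if pr.family == "normal":
        sd = pr.param("sd")
        # nearly flat normals likewise: draw from a standard normal instead
        draw_sd = 1.0 if sd > 10.0 else sd
        return pr.param("mean") + draw_sd * rng.standard_normal(spec.shape)
    raise InitializationError(f"cannot initialize prior family {pr.family!r}")


def draw_initial_values(model: HierModel, rng) -> dict:
    """Prior-based initial values with data-consistent latent states."""
    values = {}
    for spec in model.params:
        if spec.role == "latent":
            if spec.support.kind == "binary":
                values[spec.name] = rng.integers(0, 2, size=spec.shape).astype(float)
            else:
                # latent abundances: start at the forced minimum plus jitter
                maxy = model.meta.get("maxy")
                base = (np.asarray(maxy, dtype=float).reshape(spec.shape)
                        if maxy is not None and np.size(maxy) == spec.size
                        else np.zeros(spec.shape))
                values[spec.name] = base + rng.poisson(1.0, size=spec.shape)
        else:
            values[spec.name] = np.asarray(_initial_from_prior(spec, rng),
                                           dtype=float).reshape(spec.shape)
    if "suit" in values:
        values["suit"][:] = 1.0  # avoid (suit=0, N>0) contradictions at start
    return values


def run_mcmc(model: HierModel, plan: SamplerPlan, niter: int, seed: int,
             monitors=None, initial_values=None,
             max_init_tries: int = 100) -> ChainResult:
    """Run one chain; bitwise reproducible for a given seed."""
    if niter < 1:
        raise ValueError("niter must be positive")
    rng = np.random.default_rng(seed)
    if initial_values is not None:
        state = ModelState(model, initial_values)
        if not np.isfinite(state.logp):
            raise InitializationError("supplied initial values have -inf posterior")
    else:
        state = None
        for _ in range(max_init_tries):
            vals = draw_initial_values(model, rng)
            cand = ModelState(model, vals)
            if np.isfinite(cand.logp):
                state = cand
                break
        if state is None:
            raise InitializationError(
                f"no finite-posterior start in {max_init_tries} prior draws")
    samplers = build_samplers(model, plan)
    monitors = list(monitors) if monitors is not None else list(model.monitors)
    columns = []
    slots = []
    for name in monitors:
        spec = model.param_map[name]
        if spec.size == 1:
            columns.append(name)
            slots.append((name, 0))
        else:
            for i in range(spec.size):
                columns.append(f"{name}[{i}]")
                slots.append((name, i))
    samples = np.empty((niter, len(columns)))
    values = state.values
    t0 = time.perf_counter()
    for it in range(niter):
        for s in samplers:
            s.step(state, rng)
        for k, (name, i) in enumerate(slots):
            samples[it, k] = values[name].flat[i]
    loop_seconds = time.perf_counter() - t0
    return ChainResult(
        samples=samples, columns=tuple(columns), loop_seconds=loop_seconds,
        iterations=niter, seed=seed, strategy_id=plan.strategy_id,
        model_desc=dict(model.meta), sampler_summaries=[s.summary() for s in samplers],
    )


@dataclasses.dataclass
class BenchmarkCell:
    """One factorial cell: model variant x sampling strategy."""

    model_kind: str
    hierarchical: bool
    marginalize: bool
    strategy: str
    niter: int = 20000
    seed: int = 0
    scenario: str = "high"
    dims: dict = dataclasses.field(default_factory=dict)

    @property
    def cell_id(self) -> str:
        h = "+H" if self.hierarchical else "-H"
        m = "marg" if self.marginalize else "latent"
        return f"{self.model_kind}:{h}:{m}:{self.strategy}"


def run_benchmark(cells, burn_in_fraction: float = 0.1,
                  baseline: str | None = None):
    """Run every cell, returning (reports dict, combined summary DataFrame).

    Cells sharing (model_kind, scenario, seed, dims) reuse the same simulated
    dataset so strategy comparisons see identical data.  A failing cell is
    logged and skipped; it aborts only itself.
    """
    reports: dict[str, EfficiencyReport] = {}
    chains: dict[str, object] = {}
    data_cache = {}
    for cell in cells:
        try:
            cfg = ModelConfig.for_kind(cell.model_kind, **cell.dims)
            cfg.hierarchical = cell.hierarchical
            cfg.marginalize = cell.marginalize
            key = (cell.model_kind, cell.scenario, cell.seed,
                   tuple(sorted(cell.dims.items())), cell.hierarchical
                   if cell.model_kind == "nmix_zip" else None)
            if key not in data_cache:
                data_cache[key] = simulate_for(cfg, seed=cell.seed,
                                               scenario=cell.scenario)
            sim = data_cache[key]
            model = build_model(cfg, sim.data)
            plan = assign_samplers(model, cell.strategy)
            res = run_mcmc(model, plan, cell.niter, seed=cell.seed + 1)
            rep = min_efficiency(res, burn_in_fraction)
            rep.meta["cell_id"] = cell.cell_id
            reports[cell.cell_id] = rep
            chains[cell.cell_id] = res
        except Exception:
            logger.exception("benchmark cell %s failed; skipping", cell.cell_id)
    rows = []
    base_eff = (reports[baseline].min_efficiency_per_iter
                if baseline in reports else None) if baseline else None
    for cid, rep in reports.items():
        row = dict(rep.summary())
        row["cell_id"] = cid
        if base_eff:
            row["rel_ess_per_iter_vs_baseline"] = (
                rep.min_efficiency_per_iter / base_eff)
        rows.append(row)
    return reports, chains, pd.DataFrame(rows)
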