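"""Maximum composite likelihood search.

The likelihood surface is evaluated by Monte Carlo and is therefore noisy;
gradients are unreliable.  The search heuristic is accordingly two-stage and
derivative-free:

1. *global*: replicate population-based searches (differential evolution)
   inside broad user bounds, with a modest number of ARGs per evaluation;
2. *local*: replicate simplex (Nelder-Mead) refinements started at random
   points inside a box spanned by the global replicate bests (expanded 25% in
   log space), with more ARGs per evaluation;

followed by a final re-evaluation of the incumbent at a larger ARG count.
Positive-bounded parameters are searched in log space; signed parameters
(growth rates) linearly.  Infeasible points (bounds or ordering-constraint
violations) receive a sentinel objective value, so the search routes around
them rather than failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .bsfs import LUMPED, BsfsTable
from .demography import (
    DemographicModel,
    InfeasibleParametersError,
    ParameterMap,
    build_model,
)
from .likelihood import LikelihoodSettings, approximate_config_probs

__all__ = [
    "SearchSpec",
    "SearchResult",
    "global_search",
    "local_search",
    "fit",
    "default_schedule",
    "narrow_bounds",
    "watterson_theta",
    "watterson_size_bound",
]

_INFEASIBLE = 1e100


@dataclass
class SearchSpec:
    """One search stage.

    ``args_per_eval`` is the Monte-Carlo sample size per likelihood
    evaluation; ``eval_budget`` caps evaluations per replicate; ``tol_loglik``
    /``tol_param`` are the stopping tolerances of the simplex stage (the
    global stage runs out its budget).  ``reuse_draws`` applies common random
    numbers across evaluations within a replicate (variance-reduced local
    search)."""

    stage: str
    args_per_eval: int
    replicates: int = 1
    eval_budget: int = 200
    bounds: tuple[tuple[float, float], ...] | None = None
    seed: int = 0
    reuse_draws: bool = False
    tol_param: float = 1e-3
    tol_loglik: float = 0.5
    popsize: int = 8

    def __post_init__(self) -> None:
        if self.stage not in ("global", "local"):
            raise ValueError("stage must be 'global' or 'local'")
        if self.args_per_eval < 1 or self.replicates < 1:
            raise ValueError("args_per_eval and replicates must be >= 1")


@dataclass
class SearchResult:
    best_params: np.ndarray
    best_loglik: float
    trace: list[dict] = field(default_factory=list)
    final_args: int = 0
    names: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "best_params": dict(zip(self.names, self.best_params.tolist())),
            "best_loglik": self.best_loglik,
            "final_args": self.final_args,
            "trace": self.trace,
        }


class _Transform:
    """Search-space coordinates: log for positive-bounded parameters."""

    def __init__(self, pmap: ParameterMap, bounds):
        self.log = np.array(pmap.log_scale())
        b = np.asarray(bounds, dtype=float)
        self.z_bounds = np.column_stack(
            [
                np.where(self.log, np.log(np.maximum(b[:, 0], 1e-300)), b[:, 0]),
                np.where(self.log, np.log(b[:, 1]), b[:, 1]),
            ]
        )

    def to_z(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(self.log, np.log(np.maximum(x, 1e-300)), x)

    def to_x(self, z):
        z = np.asarray(z, dtype=float)
        return np.where(self.log, np.exp(z), z)


class _Objective:
    """Negative composite log-likelihood over search coordinates, with
    sentinel handling of infeasible points and per-evaluation seed flow."""

    def __init__(
        self,
        table: BsfsTable,
        template: DemographicModel,
        pmap: ParameterMap,
        transform: _Transform,
        args_per_eval: int,
        seed_seq: np.random.SeedSequence,
        reuse_draws: bool,
    ):
        self.table = table
        self.template = template
        self.pmap = pmap
        self.transform = transform
        self.args = args_per_eval
        self.reuse = reuse_draws
        self.rng = np.random.default_rng(seed_seq)
        self.fixed_seed = int(self.rng.integers(2**31 - 1))
        self.n_evals = 0
        self.n_feasible = 0
        self.last_error: str | None = None

    def _next_seed(self) -> int:
        return self.fixed_seed if self.reuse else int(self.rng.integers(2**31 - 1))

    def __call__(self, z: np.ndarray) -> float:
        self.n_evals += 1
        x = self.transform.to_x(z)
        try:
            model = build_model(x, self.pmap, self.template)
        except InfeasibleParametersError as err:
            self.last_error = str(err)
            return _INFEASIBLE
        settings = LikelihoodSettings(num_args=self.args, seed=self._next_seed())
        res = approximate_config_probs(self.table, model, settings)
        self.n_feasible += 1
        return -res.loglik

    def eval_at(self, x: np.ndarray) -> float:
        return -self(self.transform.to_z(x))


def _stage_bounds(pmap: ParameterMap, spec: SearchSpec):
    return spec.bounds if spec.bounds is not None else pmap.bounds


def _check_feasible_evals(objs: Sequence[_Objective]) -> None:
    if all(o.n_feasible == 0 for o in objs):
        msgs = {o.last_error for o in objs if o.last_error}
        raise RuntimeError(
            "every evaluated point was infeasible; binding constraints: "
            + ("; ".join(sorted(msgs)) or "unknown")
        )


def global_search(
    table: BsfsTable,
    template: DemographicModel,
    pmap: ParameterMap,
    spec: SearchSpec,
) -> SearchResult:
    """Replicate population-based (differential evolution) global searches;
    the per-replicate bests form the envelope used to narrow local bounds."""
    if spec.stage != "global":
        raise ValueError("global_search requires a global-stage spec")
    bounds = _stage_bounds(pmap, spec)
    transform = _Transform(pmap, bounds)
    D = pmap.num_params
    maxiter = max(1, spec.eval_budget // (spec.popsize * D) - 1)
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    trace = []
    objs = []
    best_x, best_ll = None, -math.inf
    for rep, seq in enumerate(seqs):
        obj = _Objective(
            table, template, pmap, transform, spec.args_per_eval, seq, spec.reuse_draws
        )
        objs.append(obj)
        de_seed = int(np.random.default_rng(seq.spawn(1)[0]).integers(2**31 - 1))
        res = differential_evolution(
            obj,
            bounds=[tuple(b) for b in transform.z_bounds],
            maxiter=maxiter,
            popsize=spec.popsize,
            tol=0.0,
            seed=de_seed,
            polish=False,
            init="latinhypercube",
        )
        x = transform.to_x(res.x)
        ll = -float(res.fun)
        trace.append(
            {
                "stage": "global",
                "replicate": rep,
                "params": x.tolist(),
                "loglik": ll,
                "n_evals": obj.n_evals,
                "n_feasible": obj.n_feasible,
                "args_per_eval": spec.args_per_eval,
            }
        )
        if ll > best_ll:
            best_x, best_ll = x, ll
    _check_feasible_evals(objs)
    return SearchResult(
        best_params=np.asarray(best_x),
        best_loglik=best_ll,
        trace=trace,
        final_args=spec.args_per_eval,
        names=pmap.names,
    )


def _random_start(transform: _Transform, box, rng) -> np.ndarray:
    lo = transform.to_z([b[0] for b in box])
    hi = transform.to_z([b[1] for b in box])
    return rng.uniform(lo, hi)


def local_search(
    table: BsfsTable,
    template: DemographicModel,
    pmap: ParameterMap,
    spec: SearchSpec,
    start_box: Sequence[tuple[float, float]] | None = None,
) -> SearchResult:
    """Replicate Nelder-Mead refinements from random starts inside
    ``start_box`` (defaults to the stage bounds).  A fully collapsed box
    degenerates to a single likelihood evaluation at that point."""
    if spec.stage != "local":
        raise ValueError("local_search requires a local-stage spec")
    bounds = _stage_bounds(pmap, spec)
    if start_box is None:
        start_box = bounds
    for (lo, hi), (blo, bhi) in zip(start_box, bounds):
        if lo < blo - 1e-12 or hi > bhi + 1e-12:
            raise ValueError("start_box must lie inside the stage bounds")
    transform = _Transform(pmap, bounds)
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.replicates)
    degenerate = all(hi <= lo for lo, hi in start_box)
    trace = []
    objs = []
    best_x, best_ll = None, -math.inf
    for rep, seq in enumerate(seqs):
        obj = _Objective(
            table, template, pmap, transform, spec.args_per_eval, seq, spec.reuse_draws
        )
        objs.append(obj)
        rng = np.random.default_rng(seq.spawn(1)[0])
        if degenerate:
            x = np.array([lo for lo, _ in start_box], dtype=float)
            ll = -obj(transform.to_z(x))
        else:
            z0 = _random_start(transform, start_box, rng)
            res = minimize(
                obj,
                z0,
                method="Nelder-Mead",
                bounds=[tuple(b) for b in transform.z_bounds],
                options={
                    "maxfev": spec.eval_budget,
                    "xatol": spec.tol_param,
                    "fatol": spec.tol_loglik,
                    "adaptive": True,
                },
            )
            x = transform.to_x(res.x)
            ll = -float(res.fun)
        trace.append(
            {
                "stage": "local",
                "replicate": rep,
                "params": np.asarray(x).tolist(),
                "loglik": ll,
                "n_evals": obj.n_evals,
                "n_feasible": obj.n_feasible,
                "args_per_eval": spec.args_per_eval,
            }
        )
        if ll > best_ll:
            best_x, best_ll = np.asarray(x), ll
    _check_feasible_evals(objs)
    return SearchResult(
        best_params=best_x,
        best_loglik=best_ll,
        trace=trace,
        final_args=spec.args_per_eval,
        names=pmap.names,
    )


def narrow_bounds(
    result: SearchResult,
    pmap: ParameterMap,
    expand: float = 0.25,
) -> tuple[tuple[float, float], ...]:
    """Bounds for the next stage: per-parameter [min, max] over replicate
    bests, expanded by ``expand`` of the spanned range on each side (in log
    space for positive parameters), clamped to the original bounds."""
    pts = np.array([t["params"] for t in result.trace], dtype=float)
    log = pmap.log_scale()
    out = []
    for j, (blo, bhi) in enumerate(pmap.bounds):
        vals = pts[:, j]
        if log[j]:
            lv = np.log(np.maximum(vals, 1e-300))
            w = max(lv.max() - lv.min(), 0.05)
            lo = math.exp(lv.min() - expand * w)
            hi = math.exp(lv.max() + expand * w)
        else:
            w = max(vals.max() - vals.min(), 1e-3 * (bhi - blo))
            lo = vals.min() - expand * w
            hi = vals.max() + expand * w
        out.append((max(lo, blo), min(hi, bhi)))
    return tuple(out)


def default_schedule(
    seed: int = 0,
    scale: float = 1.0,
    reuse_local_draws: bool = True,
) -> list[SearchSpec]:
    """The reference two-stage schedule: 10 global replicates at 5e4 ARGs per
    evaluation, then 20 local replicates at 5e5; a single ``scale`` factor
    shrinks every Monte-Carlo size for desk-scale runs (the final evaluation
    in :func:`fit` then uses 1e6 * scale ARGs)."""
    return [
        SearchSpec(
            stage="global",
            args_per_eval=max(1, int(50_000 * scale)),
            replicates=10,
            eval_budget=600,
            seed=seed,
        ),
        SearchSpec(
            stage="local",
            args_per_eval=max(1, int(500_000 * scale)),
            replicates=20,
            eval_budget=400,
            seed=seed + 1,
            reuse_draws=reuse_local_draws,
        ),
    ]


def fit(
    table: BsfsTable,
    template: DemographicModel,
    pmap: ParameterMap,
    schedule: Sequence[SearchSpec],
    final_args: int | None = None,
    final_seed: int | None = None,
) -> SearchResult:
    """Chain search stages, narrowing bounds between them, and re-evaluate
    the incumbent at ``final_args`` ARGs (default: 2x the last stage)."""
    if not schedule:
        raise ValueError("schedule must be nonempty")
    stages = list(schedule)
    if any(
        s2.stage == "global" and s1.stage == "local"
        for s1, s2 in zip(stages, stages[1:])
    ):
        raise ValueError("global stages must precede local stages")
    trace: list[dict] = []
    bounds = None
    result = None
    for spec in stages:
        if bounds is not None and spec.bounds is None:
            spec = SearchSpec(**{**spec.__dict__, "bounds": bounds})
        if spec.stage == "global":
            result = global_search(table, template, pmap, spec)
        else:
            result = local_search(table, template, pmap, spec, start_box=spec.bounds)
        trace.extend(result.trace)
        bounds = narrow_bounds(result, pmap)
    assert result is not None
    m_final = final_args if final_args is not None else 2 * stages[-1].args_per_eval
    model = build_model(result.best_params, pmap, template)
    settings = LikelihoodSettings(
        num_args=m_final,
        seed=final_seed if final_seed is not None else stages[-1].seed + 9001,
    )
    final = approximate_config_probs(table, model, settings)
    return SearchResult(
        best_params=result.best_params,
        best_loglik=final.loglik,
        trace=trace,
        final_args=m_final,
        names=pmap.names,
    )


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(table: BsfsTable) -> float:
    """Watterson's theta per block from the mean number of segregating sites
    (lumped tail entries count as ``k_max + 1``, an underestimate)."""
    n_tot = table.total_blocks
    if n_tot == 0:
        raise ValueError("empty table")
    k_max = table.lumping.k_max if table.lumping is not None else None
    s_sum = 0.0
    for config, n in table.entries.items():
        s = sum((k_max + 1) if k == LUMPED else k for k in config)
        s_sum += s * n
    return s_sum / n_tot / _harmonic(table.layout.total_samples)


def watterson_size_bound(
    table: BsfsTable, mutation_rate: float, safety: float = 10.0
) -> float:
    """Suggested upper bound (individuals) for effective-size parameters,
    ``safety * theta_W / (4 * mu * effective_length)``.  A helper only —
    never applied implicitly."""
    theta_w = watterson_theta(table)
    return safety * theta_w / (4.0 * mutation_rate * table.layout.effective_length)
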