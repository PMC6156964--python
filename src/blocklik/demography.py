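"""Parameterized demographic histories and their mapping to simulator input.

Conventions (the ms scaling throughout):

* time is measured in units of ``4 * N_ref`` generations, backwards from the
  present;
* continuous migration rates are scaled, ``M = 4 * N_ref * m`` where ``m`` is
  the per-generation fraction of a recipient population made up of migrants;
* population sizes are stored in individuals (diploids) and exposed as ratios
  to ``N_ref`` in scaled form;
* per-generation quantities (``mu``, ``r``, growth rates ``alpha``) are per
  site / per generation and unscaled.

Event semantics follow ms:

* ``split_join (derived, ancestral)`` — backwards in time all lineages in
  *derived* move to *ancestral*; migration involving *derived* ceases.
* ``size_change (pop)`` — new effective size (individuals); growth reset to 0.
* ``growth_change (pop)`` — new per-generation exponential growth rate.
* ``migration_change (donor, recipient)`` — scaled rate ``4*N_ref*m`` of
  forward-time migration donor -> recipient (lineages move recipient -> donor
  backwards in time).
* ``admixture_pulse (donor, recipient)`` — at the event time each lineage in
  *recipient* moves to *donor* (backwards in time) with probability ``f``.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import msprime
import numpy as np

__all__ = [
    "PopulationSpec",
    "DemographicEvent",
    "DemographicModel",
    "ParameterMap",
    "ScaledModel",
    "ModelError",
    "InfeasibleParametersError",
    "build_model",
    "extract_params",
    "to_scaled_units",
    "scaled_time_to_years",
    "years_to_scaled_time",
]

EVENT_KINDS = frozenset(
    {"split_join", "size_change", "growth_change", "migration_change", "admixture_pulse"}
)


class ModelError(ValueError):
    """A demographic model violates a structural invariant."""


class InfeasibleParametersError(Exception):
    """A parameter vector violates bounds or ordering constraints.

    Deliberately *not* a ``ModelError``: optimizers treat this as an
    infeasible point (sentinel likelihood) rather than a numerical failure.
    """


@dataclass
class PopulationSpec:
    """A sampled or ancestral population.

    ``initial_size`` is the effective size at the present in individuals;
    ``growth_rate`` the per-generation exponential rate (negative = decline
    forward in time).
    """

    name: str
    initial_size: float
    growth_rate: float = 0.0

    def validate(self) -> None:
        if not self.initial_size > 0:
            raise ModelError(f"population {self.name!r}: initial_size must be > 0")
        if not math.isfinite(self.growth_rate):
            raise ModelError(f"population {self.name!r}: growth_rate must be finite")


@dataclass
class DemographicEvent:
    kind: str
    time: float
    participants: tuple[str, ...]
    value: float | None = None

    def validate(self, pop_names: set[str]) -> None:
        if self.kind not in EVENT_KINDS:
            raise ModelError(f"unknown event kind {self.kind!r}")
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ModelError(f"{self.kind}: time must be finite and >= 0")
        for name in self.participants:
            if name not in pop_names:
                raise ModelError(f"{self.kind}: unknown population {name!r}")
        if self.kind == "split_join":
            if len(self.participants) != 2:
                raise ModelError("split_join needs (derived, ancestral) participants")
        elif self.kind == "size_change":
            if self.value is None or not self.value > 0:
                raise ModelError("size_change needs a positive new size")
        elif self.kind == "growth_change":
            if self.value is None or not math.isfinite(self.value):
                raise ModelError("growth_change needs a finite rate")
        elif self.kind == "migration_change":
            if len(self.participants) != 2:
                raise ModelError("migration_change needs (donor, recipient)")
            if self.value is None or self.value < 0:
                raise ModelError("migration rate must be >= 0")
        elif self.kind == "admixture_pulse":
            if len(self.participants) != 2:
                raise ModelError("admixture_pulse needs (donor, recipient)")
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ModelError("pulse fraction must be in [0, 1]")


@dataclass
class DemographicModel:
    """A full parameterized history plus per-site mutation/recombination rates.

    ``reference_size`` (``N_ref``, individuals) fixes the time and rate
    scaling; it need not equal any population's size.
    """

    populations: list[PopulationSpec]
    events: list[DemographicEvent]
    reference_size: float
    mutation_rate: float
    recombination_rate: float = 0.0

    def validate(self, require_single_root: bool = True) -> None:
        if not self.reference_size > 0:
            raise ModelError("reference_size must be > 0")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ModelError("mutation and recombination rates must be >= 0")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelError("duplicate population names")
        pop_names = set(names)
        for p in self.populations:
            p.validate()
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ModelError("events must be sorted by time")
        absorbed: set[str] = set()
        for e in self.events:
            e.validate(pop_names)
            if e.kind == "split_join":
                derived, ancestral = e.participants
                if derived in absorbed:
                    raise ModelError(f"population {derived!r} joined twice")
                if ancestral in absorbed:
                    raise ModelError(
                        f"split_join into {ancestral!r} after it was absorbed"
                    )
                absorbed.add(derived)
        roots = pop_names - absorbed
        if require_single_root and len(roots) != 1:
            raise ModelError(
                f"history must leave exactly one root lineage, found {sorted(roots)}"
            )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def copy(self) -> "DemographicModel":
        return copy.deepcopy(self)

    # -- simulator mapping ---------------------------------------------------

    def to_msprime(self) -> msprime.Demography:
        """Translate to an msprime Demography (times in generations)."""
        self.validate()
        scale = 4.0 * self.reference_size
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(
                name=p.name,
                initial_size=p.initial_size,
                growth_rate=p.growth_rate,
                initially_active=True,
            )
        names = [p.name for p in self.populations]
        for e in self.events:
            t = e.time * scale
            if e.kind == "split_join":
                derived, ancestral = e.participants
                dem.add_mass_migration(
                    time=t, source=derived, dest=ancestral, proportion=1.0
                )
                # ms semantics: migration to/from the absorbed deme ceases
                for other in names:
                    if other == derived:
                        continue
                    dem.add_migration_rate_change(
                        time=t, rate=0.0, source=derived, dest=other
                    )
                    dem.add_migration_rate_change(
                        time=t, rate=0.0, source=other, dest=derived
                    )
            elif e.kind == "size_change":
                dem.add_population_parameters_change(
                    time=t,
                    population=e.participants[0],
                    initial_size=e.value,
                    growth_rate=0.0,
                )
            elif e.kind == "growth_change":
                dem.add_population_parameters_change(
                    time=t, population=e.participants[0], growth_rate=e.value
                )
            elif e.kind == "migration_change":
                donor, recipient = e.participants
                # msprime's source is backwards-in-time: lineages move
                # recipient -> donor at per-generation rate m.
                dem.add_migration_rate_change(
                    time=t, rate=e.value / scale, source=recipient, dest=donor
                )
            elif e.kind == "admixture_pulse":
                donor, recipient = e.participants
                dem.add_mass_migration(
                    time=t, source=recipient, dest=donor, proportion=e.value
                )
        dem.sort_events()
        return dem


@dataclass(frozen=True)
class ScaledModel:
    """Event list and block rates in coalescent units (4*N_ref generations)."""

    size_ratios: dict[str, float]
    growth_rates: dict[str, float]
    events: tuple[DemographicEvent, ...]
    theta_block: float
    rho_block: float


def to_scaled_units(model: DemographicModel, block_length: int) -> ScaledModel:
    """Scaled event list plus the block mutation/recombination rates.

    ``theta_block = 4 * N_ref * mu * effective_length`` uses the callable
    length; ``rho_block = 4 * N_ref * r * (block_length - 1)`` uses the
    ``L - 1`` inter-site gaps (crossovers fall between sites).

    ``block_length`` may be an (int) effective length; pass the pair via the
    layout when they differ — see :func:`block_rates`.
    """
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    model.validate()
    nref = model.reference_size
    theta = 4.0 * nref * model.mutation_rate * block_length
    rho = 4.0 * nref * model.recombination_rate * (block_length - 1)
    return ScaledModel(
        size_ratios={p.name: p.initial_size / nref for p in model.populations},
        growth_rates={p.name: p.growth_rate for p in model.populations},
        events=tuple(copy.deepcopy(e) for e in model.events),
        theta_block=theta,
        rho_block=rho,
    )


def block_rates(model: DemographicModel, layout) -> tuple[float, float]:
    """(theta_block, rho_block) for a layout that distinguishes effective
    (callable) length from physical block length."""
    nref = model.reference_size
    theta = 4.0 * nref * model.mutation_rate * layout.effective_length
    rho = 4.0 * nref * model.recombination_rate * (layout.block_length - 1)
    return theta, rho


def scaled_time_to_years(
    t: float, reference_size: float, generation_time: float
) -> float:
    """Convert a time in 4*N_ref generations into years."""
    return t * 4.0 * reference_size * generation_time


def years_to_scaled_time(
    years: float, reference_size: float, generation_time: float
) -> float:
    return years / (4.0 * reference_size * generation_time)


# ---------------------------------------------------------------------------
# Free-parameter binding
# ---------------------------------------------------------------------------

_TARGET_RE = re.compile(
    r"^(?:(?P<scalar>reference_size|mutation_rate|recombination_rate)"
    r"|pop\[(?P<pop>[^\]]+)\]\.(?P<pfield>initial_size|growth_rate)"
    r"|event\[(?P<idx>\d+)\]\.(?P<efield>time|value))$"
)


def _resolve(model: DemographicModel, target: str):
    m = _TARGET_RE.match(target)
    if m is None:
        raise ValueError(f"malformed binding target {target!r}")
    if m["scalar"]:
        return model, m["scalar"]
    if m["pop"]:
        return model.population(m["pop"]), m["pfield"]
    idx = int(m["idx"])
    if idx >= len(model.events):
        raise ValueError(f"binding target {target!r}: no such event")
    return model.events[idx], m["efield"]


Constraint = tuple[str, str, str] | Callable[[dict[str, float]], bool]


@dataclass
class ParameterMap:
    """Binds an ordered flat parameter vector to model fields.

    ``bind[name]`` is a tuple of target paths (``"reference_size"``,
    ``"pop[S].initial_size"``, ``"event[2].time"`` ...); a parameter may drive
    several fields (e.g. one size shared by every daughter population).

    ``constraints`` are ordering rules, either declarative triples
    ``("T2", "<", "T")`` or callables mapping the named parameter dict to a
    bool; violations make a point *infeasible*, not erroneous.
    """

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    bind: dict[str, tuple[str, ...]]
    constraints: tuple[Constraint, ...] = ()

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(self.names) != len(self.bounds):
            raise ValueError("names and bounds length mismatch")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"parameter {name!r}: lower bound must be < upper")
        missing = [n for n in self.names if n not in self.bind or not self.bind[n]]
        if missing:
            raise ValueError(f"unbound parameters: {missing}")
        extra = set(self.bind) - set(self.names)
        if extra:
            raise ValueError(f"bindings for unknown parameters: {sorted(extra)}")

    @property
    def num_params(self) -> int:
        return len(self.names)

    def log_scale(self) -> tuple[bool, ...]:
        """Search-space hint: positive-bounded parameters are searched in log
        space, signed ones (growth rates) linearly."""
        return tuple(lo > 0 for lo, _ in self.bounds)

    def check_feasible(self, params: Sequence[float]) -> None:
        params = np.asarray(params, dtype=float)
        if params.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} parameters, got shape {params.shape}"
            )
        named = dict(zip(self.names, params.tolist()))
        for (lo, hi), name in zip(self.bounds, self.names):
            v = named[name]
            if not (math.isfinite(v) and lo <= v <= hi):
                raise InfeasibleParametersError(
                    f"{name}={v} outside bounds [{lo}, {hi}]"
                )
        for con in self.constraints:
            if callable(con):
                if not con(named):
                    raise InfeasibleParametersError(f"constraint {con} violated")
            else:
                lhs, op, rhs = con
                a, b = named[lhs], named[rhs]
                ok = a < b if op == "<" else a <= b if op == "<=" else None
                if ok is None:
                    raise ValueError(f"unsupported constraint operator {op!r}")
                if not ok:
                    raise InfeasibleParametersError(
                        f"ordering constraint {lhs} {op} {rhs} violated "
                        f"({a} vs {b})"
                    )


def build_model(
    params: Sequence[float], pmap: ParameterMap, template: DemographicModel
) -> DemographicModel:
    """Bind a flat parameter vector into a copy of the template.

    Raises :class:`InfeasibleParametersError` for out-of-bounds or
    ordering-constraint violations (the optimizer's sentinel) and
    :class:`ModelError` for structural problems in the resulting model.
    """
    pmap.check_feasible(params)
    model = template.copy()
    for name, value in zip(pmap.names, np.asarray(params, dtype=float)):
        for target in pmap.bind[name]:
            obj, fieldname = _resolve(model, target)
            setattr(obj, fieldname, float(value))
    times = [e.time for e in model.events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        # Bound times invert the template's event order: an ill-ordered
        # proposal, not a structural defect of the template.
        raise InfeasibleParametersError("bound event times out of order")
    model.validate()
    return model


def extract_params(model: DemographicModel, pmap: ParameterMap) -> np.ndarray:
    """Read the flat parameter vector back from a bound model (first target
    of each binding; round-trips :func:`build_model` exactly)."""
    out = np.empty(len(pmap.names))
    for i, name in enumerate(pmap.names):
        obj, fieldname = _resolve(model, pmap.bind[name][0])
        out[i] = getattr(obj, fieldname)
    return out
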