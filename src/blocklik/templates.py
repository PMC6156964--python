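"""Ready-made demographic templates.

Two families are provided:

* the nested two-population divergence models ``m1`` ... ``m6`` (clean split;
  distinct daughter sizes; exponential growth; continuous uni-epoch or
  two-epoch migration; bidirectional admixture pulse) used for fitting, each
  returning a ``(template, ParameterMap)`` pair whose free-parameter set
  matches the family definition (r, the per-site recombination rate, is a free
  parameter unless ``free_r=False``);
* three small fixed histories with known analytic blockwise spectra, used for
  validating the Monte-Carlo machinery: a single population with a stepwise
  size change, a two-population isolation-with-migration (IM) history and a
  three-population isolation-with-unidirectional-admixture (IUA) history.
  Their time arguments are accepted in the literature's 2*N_e units and
  converted to the internal 4*N_ref scale (divided by two) to prevent silent
  factor-2 errors.

In the fitting family, times are in units of ``4 * N_ref`` generations where
``N_ref`` is frozen at the construction-time ancestral size; sizes are in
individuals.  The two populations are labelled ``S`` and ``B``; migration
rates are scaled ``4 * N_ref * m``, pulse fractions are forward-time donor ->
recipient.
"""

from __future__ import annotations

from .demography import (
    DemographicEvent,
    DemographicModel,
    ParameterMap,
    PopulationSpec,
)

__all__ = [
    "m1",
    "m2",
    "m3",
    "m4",
    "m5",
    "m6",
    "single_population",
    "size_change_model",
    "im_model",
    "iua_model",
]

_SIZE_BOUNDS = (50.0, 1e6)
_TIME_BOUNDS = (0.01, 25.0)
_T2_BOUNDS = (0.005, 25.0)
_R_BOUNDS = (1e-10, 5e-7)
_MIG_BOUNDS = (0.0, 50.0)
_FRAC_BOUNDS = (0.0, 1.0)
_GROWTH_BOUNDS = (-1e-2, 1e-2)


def _finish(model, names, bounds, bind, constraints=(), *, free_r, bounds_override):
    if free_r:
        names = names + ("r",)
        bounds = bounds + (_R_BOUNDS,)
        bind = dict(bind, r=("recombination_rate",))
    if bounds_override:
        bounds = tuple(
            bounds_override.get(n, b) for n, b in zip(names, bounds)
        )
    pmap = ParameterMap(
        names=names, bounds=bounds, bind=bind, constraints=tuple(constraints)
    )
    model.validate()
    return model, pmap


def m1(
    n_a: float = 1400.0,
    t: float = 2.0,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """Clean split at ``t``; every population (both daughters and the
    ancestor) has size ``n_a``.  Free parameters: N_A, T (and r)."""
    model = DemographicModel(
        populations=[PopulationSpec("S", n_a), PopulationSpec("B", n_a)],
        events=[DemographicEvent("split_join", t, ("B", "S"))],
        reference_size=n_a,
        mutation_rate=mu,
        recombination_rate=r,
    )
    return _finish(
        model,
        names=("N_A", "T"),
        bounds=(_SIZE_BOUNDS, _TIME_BOUNDS),
        bind={
            "N_A": ("pop[S].initial_size", "pop[B].initial_size"),
            "T": ("event[0].time",),
        },
        free_r=free_r,
        bounds_override=bounds,
    )


def _split_core(n_a, n_s, n_b, t, mu, r):
    """Populations S, B with distinct sizes; at ``t`` B joins S and the merged
    population takes the ancestral size ``n_a``."""
    return DemographicModel(
        populations=[PopulationSpec("S", n_s), PopulationSpec("B", n_b)],
        events=[
            DemographicEvent("split_join", t, ("B", "S")),
            DemographicEvent("size_change", t, ("S",), n_a),
        ],
        reference_size=n_a,
        mutation_rate=mu,
        recombination_rate=r,
    )


def m2(
    n_a: float = 1400.0,
    n_s: float = 22000.0,
    n_b: float = 8600.0,
    t: float = 2.5,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """Split with three distinct sizes.  Free: N_A, N_S, N_B, T (and r)."""
    model = _split_core(n_a, n_s, n_b, t, mu, r)
    return _finish(
        model,
        names=("N_A", "N_S", "N_B", "T"),
        bounds=(_SIZE_BOUNDS, _SIZE_BOUNDS, _SIZE_BOUNDS, _TIME_BOUNDS),
        bind={
            "N_A": ("event[1].value",),
            "N_S": ("pop[S].initial_size",),
            "N_B": ("pop[B].initial_size",),
            "T": ("event[0].time", "event[1].time"),
        },
        free_r=free_r,
        bounds_override=bounds,
    )


def m3(
    n_a: float = 2200.0,
    n_s: float = 22000.0,
    n_b: float = 5500.0,
    t: float = 2.5,
    alpha_s: float = 0.0,
    alpha_b: float = 0.0,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """M2 plus exponential growth/decline (per-generation rates, signed) in
    each daughter population.  Free: N_A, N_S, N_B, alpha_S, alpha_B, T (+ r).
    """
    model = _split_core(n_a, n_s, n_b, t, mu, r)
    model.population("S").growth_rate = alpha_s
    model.population("B").growth_rate = alpha_b
    return _finish(
        model,
        names=("N_A", "N_S", "N_B", "alpha_S", "alpha_B", "T"),
        bounds=(
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _GROWTH_BOUNDS,
            _GROWTH_BOUNDS,
            _TIME_BOUNDS,
        ),
        bind={
            "N_A": ("event[1].value",),
            "N_S": ("pop[S].initial_size",),
            "N_B": ("pop[B].initial_size",),
            "alpha_S": ("pop[S].growth_rate",),
            "alpha_B": ("pop[B].growth_rate",),
            "T": ("event[0].time", "event[1].time"),
        },
        free_r=free_r,
        bounds_override=bounds,
    )


def m4(
    n_a: float = 1300.0,
    n_s: float = 22000.0,
    n_b: float = 8200.0,
    t: float = 2.5,
    mig_sb: float = 0.05,
    mig_bs: float = 0.05,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """Isolation with continuous asymmetric migration from the split to the
    present.  Rates are scaled, ``4*N_ref*m``, forward-time donor->recipient.
    Free: N_A, N_S, N_B, M_SB, M_BS, T (+ r)."""
    model = _split_core(n_a, n_s, n_b, t, mu, r)
    model.events = [
        DemographicEvent("migration_change", 0.0, ("S", "B"), mig_sb),
        DemographicEvent("migration_change", 0.0, ("B", "S"), mig_bs),
    ] + model.events
    return _finish(
        model,
        names=("N_A", "N_S", "N_B", "M_SB", "M_BS", "T"),
        bounds=(
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _MIG_BOUNDS,
            _MIG_BOUNDS,
            _TIME_BOUNDS,
        ),
        bind={
            "N_A": ("event[3].value",),
            "N_S": ("pop[S].initial_size",),
            "N_B": ("pop[B].initial_size",),
            "M_SB": ("event[0].value",),
            "M_BS": ("event[1].value",),
            "T": ("event[2].time", "event[3].time"),
        },
        free_r=free_r,
        bounds_override=bounds,
    )


def m5(
    n_a: float = 1300.0,
    n_s: float = 21600.0,
    n_b: float = 8900.0,
    t: float = 6.0,
    t2: float = 1.0,
    mig_sb: float = 1.5,
    mig_bs: float = 2.2,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """Isolation with initial migration: gene flow from the split until it
    ceases at ``t2`` (forward time), so backwards in time migration is active
    on ``[t2, t]``.  Enforces T2 < T.  Free: N_A, N_S, N_B, M_SB, M_BS, T_2,
    T (+ r)."""
    if not t2 < t:
        raise ValueError("m5 requires t2 < t")
    model = _split_core(n_a, n_s, n_b, t, mu, r)
    model.events = [
        DemographicEvent("migration_change", t2, ("S", "B"), mig_sb),
        DemographicEvent("migration_change", t2, ("B", "S"), mig_bs),
    ] + model.events
    return _finish(
        model,
        names=("N_A", "N_S", "N_B", "M_SB", "M_BS", "T_2", "T"),
        bounds=(
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _MIG_BOUNDS,
            _MIG_BOUNDS,
            _T2_BOUNDS,
            _TIME_BOUNDS,
        ),
        bind={
            "N_A": ("event[3].value",),
            "N_S": ("pop[S].initial_size",),
            "N_B": ("pop[B].initial_size",),
            "M_SB": ("event[0].value",),
            "M_BS": ("event[1].value",),
            "T_2": ("event[0].time", "event[1].time"),
            "T": ("event[2].time", "event[3].time"),
        },
        constraints=(("T_2", "<", "T"),),
        free_r=free_r,
        bounds_override=bounds,
    )


def m6(
    n_a: float = 1400.0,
    n_s: float = 22400.0,
    n_b: float = 8900.0,
    t: float = 7.0,
    t2: float = 2.6,
    f_sb: float = 0.12,
    f_bs: float = 0.27,
    *,
    mu: float = 2e-8,
    r: float = 2e-8,
    free_r: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
):
    """Split at ``t`` followed by a bidirectional instantaneous admixture
    pulse at ``t2 < t``: a fraction ``f_sb`` of B descends from S via the
    pulse and ``f_bs`` vice versa.  Free: N_A, N_S, N_B, T_2, f_SB, f_BS,
    T (+ r)."""
    if not t2 < t:
        raise ValueError("m6 requires t2 < t")
    model = _split_core(n_a, n_s, n_b, t, mu, r)
    model.events = [
        DemographicEvent("admixture_pulse", t2, ("S", "B"), f_sb),
        DemographicEvent("admixture_pulse", t2, ("B", "S"), f_bs),
    ] + model.events
    return _finish(
        model,
        names=("N_A", "N_S", "N_B", "T_2", "f_SB", "f_BS", "T"),
        bounds=(
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _SIZE_BOUNDS,
            _T2_BOUNDS,
            _FRAC_BOUNDS,
            _FRAC_BOUNDS,
            _TIME_BOUNDS,
        ),
        bind={
            "N_A": ("event[3].value",),
            "N_S": ("pop[S].initial_size",),
            "N_B": ("pop[B].initial_size",),
            "T_2": ("event[0].time", "event[1].time"),
            "f_SB": ("event[0].value",),
            "f_BS": ("event[1].value",),
            "T": ("event[2].time", "event[3].time"),
        },
        constraints=(("T_2", "<", "T"),),
        free_r=free_r,
        bounds_override=bounds,
    )


# ---------------------------------------------------------------------------
# Fixed small histories with known analytic blockwise spectra
# ---------------------------------------------------------------------------


def single_population(
    ne: float = 10000.0,
    *,
    mu: float = 2e-8,
    r: float = 0.0,
    bounds: tuple[float, float] = (100.0, 1e6),
):
    """One constant-size panmictic population; the effective size is the only
    free parameter (equivalently the block mutation rate theta)."""
    model = DemographicModel(
        populations=[PopulationSpec("P", ne)],
        events=[],
        reference_size=ne,
        mutation_rate=mu,
        recombination_rate=r,
    )
    pmap = ParameterMap(
        names=("N",),
        bounds=(bounds,),
        bind={"N": ("pop[P].initial_size", "reference_size")},
    )
    model.validate()
    return model, pmap


def size_change_model(
    ne: float = 10000.0,
    ancient_ratio: float = 0.5,
    t: float = 0.2,
    *,
    mu: float = 2e-8,
    r: float = 0.0,
) -> DemographicModel:
    """Single population whose size stepped from ``ancient_ratio * ne`` to
    ``ne`` at time ``t`` (given in 2*N_e units, as the analytic literature
    states it; converted internally)."""
    model = DemographicModel(
        populations=[PopulationSpec("P", ne)],
        events=[DemographicEvent("size_change", t / 2.0, ("P",), ancient_ratio * ne)],
        reference_size=ne,
        mutation_rate=mu,
        recombination_rate=r,
    )
    model.validate()
    return model


def im_model(
    ne: float = 10000.0,
    t: float = 1.2,
    mig: float = 0.5,
    *,
    mu: float = 2e-8,
    r: float = 0.0,
) -> DemographicModel:
    """Two equal-size populations A and B that split at ``t`` (2*N_e units)
    with continuous unidirectional migration at scaled rate
    ``M = 4*N_e*m`` migrants per generation from A to B (forward time)."""
    model = DemographicModel(
        populations=[PopulationSpec("A", ne), PopulationSpec("B", ne)],
        events=[
            DemographicEvent("migration_change", 0.0, ("A", "B"), mig),
            DemographicEvent("split_join", t / 2.0, ("B", "A")),
        ],
        reference_size=ne,
        mutation_rate=mu,
        recombination_rate=r,
    )
    model.validate()
    return model


def iua_model(
    ne: float = 10000.0,
    f: float = 0.06,
    t_gf: float = 0.125,
    t_1: float = 0.15,
    t_2: float = 0.6,
    *,
    mu: float = 2e-8,
    r: float = 0.0,
) -> DemographicModel:
    """Three equal-size populations: A and B split at ``t_1``, their ancestor
    and C at ``t_2``, with an instantaneous unidirectional admixture pulse
    moving a fraction ``f`` of B's ancestry from A at ``t_gf`` (all times in
    2*N_e units; requires t_gf < t_1 < t_2)."""
    if not t_gf < t_1 < t_2:
        raise ValueError("iua_model requires t_gf < t_1 < t_2")
    model = DemographicModel(
        populations=[
            PopulationSpec("A", ne),
            PopulationSpec("B", ne),
            PopulationSpec("C", ne),
        ],
        events=[
            DemographicEvent("admixture_pulse", t_gf / 2.0, ("A", "B"), f),
            DemographicEvent("split_join", t_1 / 2.0, ("B", "A")),
            DemographicEvent("split_join", t_2 / 2.0, ("C", "A")),
        ],
        reference_size=ne,
        mutation_rate=mu,
        recombination_rate=r,
    )
    model.validate()
    return model
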