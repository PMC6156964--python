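"""Demographic model construction, parameter binding, scaling, ms round-trip."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blocklik import (
    DemographicEvent,
    DemographicModel,
    InfeasibleParametersError,
    ModelError,
    PopulationSpec,
    build_model,
    extract_params,
    to_scaled_units,
)
from blocklik.demography import (
    block_rates,
    scaled_time_to_years,
    years_to_scaled_time,
)
from blocklik.classes import SampleLayout
from blocklik.msformat import parse_ms_args, to_ms_args
from blocklik import templates


@pytest.mark.parametrize(
    "factory,n_free",
    [
        (templates.m1, 3),
        (templates.m2, 5),
        (templates.m3, 7),
        (templates.m4, 7),
        (templates.m5, 8),
        (templates.m6, 8),
    ],
)
def test_template_free_parameter_counts(factory, n_free):
    """Each nested divergence model exposes its family's free-parameter set
    (recombination rate included)."""
    model, pmap = factory()
    assert pmap.num_params == n_free
    model.validate()


def test_m1_daughters_share_ancestral_size():
    model, pmap = templates.m1(free_r=False)
    bound = build_model([5000.0, 1.5], pmap, model)
    assert bound.population("S").initial_size == 5000.0
    assert bound.population("B").initial_size == 5000.0
    assert [e.kind for e in bound.events] == ["split_join"]
    assert bound.events[0].time == 1.5


def test_m2_has_exactly_one_split_join():
    model, pmap = templates.m2()
    assert sum(e.kind == "split_join" for e in model.events) == 1


def test_m6_ordering_constraint_is_infeasible_not_error():
    model, pmap = templates.m6(free_r=False)
    good = [1400.0, 22000.0, 8900.0, 2.0, 0.1, 0.2, 7.0]
    build_model(good, pmap, model)
    bad = good.copy()
    bad[3] = 8.0  # admixture older than the split
    with pytest.raises(InfeasibleParametersError):
        build_model(bad, pmap, model)


def test_out_of_bounds_is_infeasible():
    model, pmap = templates.m1(free_r=False)
    with pytest.raises(InfeasibleParametersError):
        build_model([1e12, 1.0], pmap, model)


@pytest.mark.parametrize("factory", [templates.m2, templates.m5, templates.m6])
def test_build_extract_round_trip(factory):
    """Reading back the flat vector from a bound model is bit-for-bit."""
    model, pmap = factory()
    rng = np.random.default_rng(7)
    lo = np.array([b[0] for b in pmap.bounds])
    hi = np.array([b[1] for b in pmap.bounds])
    for _ in range(20):
        x = lo + rng.random(len(lo)) * (hi - lo)
        named = dict(zip(pmap.names, x))
        if "T_2" in named:
            named["T_2"] = min(named["T_2"], 0.9 * named["T"])
            x = np.array([named[n] for n in pmap.names])
        bound = build_model(x, pmap, model)
        assert np.array_equal(extract_params(bound, pmap), x)


def test_scaled_units_theta_and_rho():
    model = DemographicModel(
        populations=[PopulationSpec("P", 1250.0)],
        events=[],
        reference_size=1250.0,
        mutation_rate=2e-8,
        recombination_rate=0.0,
    )
    scaled = to_scaled_units(model, 2000)
    assert scaled.theta_block == pytest.approx(4 * 1250 * 2e-8 * 2000)  # 0.2
    assert scaled.rho_block == 0.0
    layout = SampleLayout((2,), block_length=2000, effective_length=1600)
    theta, rho = block_rates(model, layout)
    assert theta == pytest.approx(0.16)


def test_rho_uses_inter_site_gaps():
    model = DemographicModel(
        populations=[PopulationSpec("P", 1000.0)],
        events=[],
        reference_size=1000.0,
        mutation_rate=1e-8,
        recombination_rate=1e-8,
    )
    assert to_scaled_units(model, 2000).rho_block == pytest.approx(
        4 * 1000 * 1e-8 * 1999
    )


@given(st.floats(min_value=1e-3, max_value=50.0))
def test_year_conversion_round_trip(t):
    assert years_to_scaled_time(
        scaled_time_to_years(t, 1250.0, 20.0), 1250.0, 20.0
    ) == pytest.approx(t, rel=1e-12)


def test_doubling_nref_halving_scaled_times_is_invariant():
    """The unscaled (generation-time) model is unchanged when N_ref doubles
    and all scaled times halve."""

    def gen_times(nref, t):
        model = DemographicModel(
            populations=[PopulationSpec("S", 5000.0), PopulationSpec("B", 3000.0)],
            events=[DemographicEvent("split_join", t, ("B", "S"))],
            reference_size=nref,
            mutation_rate=2e-8,
        )
        dem = model.to_msprime()
        return [e.time for e in dem.events]

    assert gen_times(1000.0, 2.0) == gen_times(2000.0, 1.0)


def test_validate_rejects_structural_defects():
    pops = [PopulationSpec("S", 100.0), PopulationSpec("B", 100.0)]
    with pytest.raises(ModelError, match="sorted"):
        DemographicModel(
            populations=pops,
            events=[
                DemographicEvent("size_change", 2.0, ("S",), 50.0),
                DemographicEvent("split_join", 1.0, ("B", "S")),
            ],
            reference_size=100.0,
            mutation_rate=1e-8,
        ).validate()
    with pytest.raises(ModelError, match="unknown population"):
        DemographicModel(
            populations=pops,
            events=[DemographicEvent("split_join", 1.0, ("B", "X"))],
            reference_size=100.0,
            mutation_rate=1e-8,
        ).validate()
    with pytest.raises(ModelError, match="root"):
        DemographicModel(
            populations=pops,
            events=[],
            reference_size=100.0,
            mutation_rate=1e-8,
        ).validate()


def test_pulse_fraction_bounds():
    with pytest.raises(ModelError):
        DemographicEvent("admixture_pulse", 1.0, ("A", "B"), 1.5).validate({"A", "B"})


@pytest.mark.parametrize(
    "factory",
    [templates.m2, templates.m4, templates.m6, templates.m3],
)
def test_ms_string_round_trip(factory):
    """model -> ms args -> model preserves the event list and rates."""
    model, _ = factory()
    back = parse_ms_args(
        to_ms_args(model),
        model.reference_size,
        model.mutation_rate,
        model.recombination_rate,
    )
    assert len(back.populations) == len(model.populations)
    for p, q in zip(model.populations, back.populations):
        assert q.initial_size == pytest.approx(p.initial_size)
        assert q.growth_rate == pytest.approx(p.growth_rate)
    assert len(back.events) == len(model.events)
    for e, f in zip(model.events, back.events):
        assert (f.kind, f.time) == (e.kind, pytest.approx(e.time))
        if e.value is not None:
            assert f.value == pytest.approx(e.value)


def test_fig2_templates_take_2ne_units():
    im = templates.im_model(t=1.2)
    assert im.events[-1].time == pytest.approx(0.6)  # internal 4Ne units
    iua = templates.iua_model()
    assert [e.time for e in iua.events] == pytest.approx([0.0625, 0.075, 0.3])
    step = templates.size_change_model(t=0.2, ancient_ratio=0.5, ne=10000)
    assert step.events[0].time == pytest.approx(0.1)
    assert step.events[0].value == pytest.approx(5000.0)
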