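"""Synthetic blockwise datasets and the experiment drivers."""

import numpy as np
import pytest

from blocklik import (
    BsfsTable,
    SampleLayout,
    SearchSpec,
    SimulationSpec,
    parametric_bootstrap,
    simulate_bsfs,
    simulate_dataset,
    misspecification_experiment,
)
from blocklik import templates


@pytest.fixture(scope="module")
def pair_layout():
    return SampleLayout((2,), block_length=1000)


def test_zero_mutation_rate_gives_all_monomorphic(pair_layout):
    model, _ = templates.single_population(ne=10000.0, mu=0.0)
    table = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=200, seed=1)
    )
    assert table.entries == {(0,): 200}


def test_stretch_equal_to_block_length_matches_unlinked(pair_layout):
    model, _ = templates.single_population(ne=10000.0, mu=2e-8, r=1e-8)
    unlinked = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=300, seed=4)
    )
    degenerate = simulate_bsfs(
        SimulationSpec(
            model=model, layout=pair_layout, num_blocks=300, linkage=1000, seed=4
        )
    )
    assert unlinked.entries == degenerate.entries


def test_simulated_spectrum_matches_geometric_law(pair_layout):
    """b=2, rho=0, unlinked blocks: empirical configuration frequencies match
    P(k) = theta^k / (1+theta)^(k+1) within multinomial error (the end-to-end
    check of the mutation-placement path)."""
    model, _ = templates.single_population(ne=6250.0, mu=2e-8)  # theta_block 0.5
    n = 10000
    table = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=n, seed=29)
    )
    theta = 0.5
    for k in range(5):
        p = theta**k / (1 + theta) ** (k + 1)
        se = np.sqrt(p * (1 - p) / n)
        obs = table.entries.get((k,), 0) / n
        assert abs(obs - p) < 4 * se


def test_counts_path_matches_genotype_path_distribution(pair_layout):
    """Direct Poisson class-count draws agree with msprime mutation placement
    (two independent routes to the same blockwise distribution)."""
    model, _ = templates.single_population(ne=6250.0, mu=2e-8, r=1e-8)
    n = 4000
    geno = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=n, seed=61)
    )
    cnts = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=n, seed=62),
        method="counts",
    )

    def mean_and_se(table):
        ks = np.array([k for (k,), c in table.entries.items() for _ in range(0)])
        total = table.total_blocks
        mean = sum(k * c for (k,), c in table.entries.items()) / total
        var = (
            sum(k**2 * c for (k,), c in table.entries.items()) / total - mean**2
        )
        return mean, np.sqrt(var / total)

    m1, s1 = mean_and_se(geno)
    m2, s2 = mean_and_se(cnts)
    assert abs(m1 - m2) < 4 * np.hypot(s1, s2)


def test_mean_diversity_matches_theta(pair_layout):
    """Mean pairwise differences per block equal theta_block within 3 SE."""
    model, _ = templates.single_population(ne=6250.0, mu=2e-8)
    n = 10000
    table = simulate_bsfs(
        SimulationSpec(model=model, layout=pair_layout, num_blocks=n, seed=43)
    )
    ks = np.array([k for (k,), c in table.entries.items()])
    cs = np.array([c for (k,), c in table.entries.items()])
    mean = (ks * cs).sum() / n
    var = (ks**2 * cs).sum() / n - mean**2
    assert abs(mean - 0.5) < 3 * np.sqrt(var / n)


def test_simulation_reproducible_from_seed(pair_layout):
    model, _ = templates.single_population(ne=5000.0, mu=2e-8, r=1e-8)
    spec = SimulationSpec(model=model, layout=pair_layout, num_blocks=100, seed=77)
    a = [b.tolist() for b in simulate_dataset(spec)]
    b = [b.tolist() for b in simulate_dataset(spec)]
    assert a == b


def test_stretches_validate_multiples(pair_layout):
    model, _ = templates.single_population()
    with pytest.raises(ValueError, match="multiple"):
        SimulationSpec(model=model, layout=pair_layout, num_blocks=10, linkage=1500)


def test_degenerate_bootstrap_has_zero_sd(pair_layout):
    """A collapsed local box makes every replicate return the same point:
    the SD estimate must be exactly zero."""
    model, pmap = templates.single_population(ne=8000.0, mu=2e-8)
    point = np.array([8000.0])
    sim = SimulationSpec(model=model, layout=pair_layout, num_blocks=50, seed=5)
    local = SearchSpec(
        stage="local",
        args_per_eval=20,
        replicates=1,
        eval_budget=10,
        seed=1,
        bounds=((8000.0, 8000.0 + 1e-9),),
    )
    # start box collapsed to the point itself
    local.bounds = ((8000.0, 8000.0),)
    boot = parametric_bootstrap(
        point, model, pmap, sim, replicates=3, local_spec=local, sim_method="counts"
    )
    assert np.all(boot.sd == 0.0)
    assert boot.ci[0, 0] == boot.ci[0, 1] == 8000.0
    assert boot.num_replicates == 3


def test_misspecification_prefers_richer_point_model(pair_layout):
    """Data simulated under a two-epoch history fits its own parameter values
    at least as well (in median) as a constant-size history evaluated at the
    same current size."""
    two_epoch = templates.size_change_model(ne=10000.0, ancient_ratio=0.1, t=0.2)
    flat, _ = templates.single_population(ne=10000.0)
    out = misspecification_experiment(
        true_models={"step": two_epoch},
        fit_models={},
        datasets_per_model=3,
        layout=pair_layout,
        num_blocks=2000,
        seed=9,
        point_models={"truth": two_epoch, "flat": flat},
        point_args=400,
        sim_method="counts",
    )
    truth_ll = np.median(out["point"][("step", "truth")])
    flat_ll = np.median(out["point"][("step", "flat")])
    assert truth_ll > flat_ll


def test_misspecification_single_pair_reduces_to_fit(pair_layout):
    model, pmap = templates.single_population(ne=10000.0)
    calls = []

    def fake_fit(table, tmpl, pm, schedule):
        calls.append(table.total_blocks)
        from blocklik.inference import SearchResult

        return SearchResult(
            best_params=np.array([1.0]), best_loglik=-1.0, names=pm.names
        )

    out = misspecification_experiment(
        true_models={"m": model},
        fit_models={"m": (model, pmap, [])},
        datasets_per_model=2,
        layout=pair_layout,
        num_blocks=100,
        seed=3,
        fitter=fake_fit,
        sim_method="counts",
    )
    assert out["fit"][("m", "m")] == [-1.0, -1.0]
    assert calls == [100, 100]
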