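"""Mutation-class combinatorics, configuration enumeration, tabulation,
subsampling, and table serialization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blocklik import (
    LUMPED,
    BsfsTable,
    LumpingSpec,
    SampleLayout,
    SubsamplingScheme,
    build_cbsfs,
    enumerate_configurations,
    num_site_types,
    read_table,
    tabulate,
    write_table,
)
from blocklik.bsfs import compatible_class_sets, fold_table
from blocklik.classes import ClassIndex, fold_vector


# ---------------------------------------------------------------------------
# Independent oracle: enumerate labeled rooted binary topologies recursively
# over leaf bipartitions (a different algorithm from the production
# coalescent-merge enumeration) and derive their branch-class sets.
# ---------------------------------------------------------------------------


def _oracle_topologies(leaves):
    leaves = tuple(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in _oracle_topologies(left):
                for rt in _oracle_topologies(right):
                    yield (lt, rt)


def _oracle_class_sets(layout):
    """Branch-class sets of every labeled topology (leaves tagged by
    population); classes are canonical folded/unfolded vectors."""
    X = layout.num_populations
    leaves = []
    for x, b in enumerate(layout.sizes):
        leaves.extend([(x, i) for i in range(b)])

    def leaf_vec(leaf):
        return tuple(1 if leaf[0] == x else 0 for x in range(X))

    def collect(node, acc):
        if isinstance(node, tuple) and len(node) == 2 and isinstance(node[0], (tuple,)) and not (
            len(node) == 2 and isinstance(node[0], int)
        ):
            l_vec = collect(node[0], acc)
            r_vec = collect(node[1], acc)
            vec = tuple(a + b for a, b in zip(l_vec, r_vec))
        else:
            vec = leaf_vec(node)
        acc.append(vec)
        return vec

    sets = set()
    for topo in _oracle_topologies(leaves):
        acc = []
        collect(topo, acc)
        acc = acc[:-1]  # the last vector is the root: not a branch
        canon = {
            v if layout.polarized else fold_vector(v, layout.sizes) for v in acc
        }
        sets.add(frozenset(canon))
    return sets


def _oracle_count(layout, k_max):
    sets = _oracle_class_sets(layout)
    classes = ClassIndex(layout).classes
    values = list(range(k_max + 1)) + [LUMPED]
    count = 0
    for cfg in itertools.product(values, repeat=len(classes)):
        positive = frozenset(c for c, k in zip(classes, cfg) if k != 0)
        if any(positive <= s for s in sets):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Class combinatorics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sizes,polarized,expected",
    [
        ((2, 2), True, 7),  # prod(b+1) - 2
        ((2, 2), False, 4),
        ((4,), False, 2),
        ((4,), True, 3),
        ((1, 1, 1), True, 6),
    ],
)
def test_num_site_types(sizes, polarized, expected):
    lay = SampleLayout(sizes, block_length=100, polarized=polarized)
    assert num_site_types(lay) == expected


def test_folding_is_involutive_on_vectors():
    sizes = (2, 3)
    for vec in itertools.product(range(3), range(4)):
        f = fold_vector(vec, sizes)
        assert fold_vector(f, sizes) == f


def test_enumeration_counts(layout22):
    ls = LumpingSpec(4)
    assert len(enumerate_configurations(layout22, ls)) == 6**4
    assert len(enumerate_configurations(layout22, ls, no_recombination=True)) == 396
    single = SampleLayout((2,), block_length=100)
    assert [c for c in enumerate_configurations(single, ls)] == [
        (0,),
        (1,),
        (2,),
        (3,),
        (4,),
        (LUMPED,),
    ]


def test_enumeration_cardinality_scaling():
    """(k_max + 2)^C without the single-genealogy exclusion."""
    for sizes, k_max in [((2,), 2), ((3,), 3), ((2, 2), 1)]:
        lay = SampleLayout(sizes, block_length=100)
        C = num_site_types(lay)
        assert len(enumerate_configurations(lay, LumpingSpec(k_max))) == (
            k_max + 2
        ) ** C


def test_compatible_sets_match_topology_oracle(layout22):
    """Production coalescent-merge enumeration agrees with the independent
    bipartition-recursion oracle, including the headline (2,2) count."""
    assert set(compatible_class_sets(layout22)) == _oracle_class_sets(layout22)
    assert _oracle_count(layout22, 4) == 396
    lay3 = SampleLayout((3, 1), block_length=100)
    assert set(compatible_class_sets(lay3)) == _oracle_class_sets(lay3)


def test_shared_and_fixed_never_cooccur_without_recombination(layout22):
    """No single 4-leaf genealogy carries both the shared-polymorphism and
    the fixed-difference class (exhaustive over labeled topologies)."""
    shared, fixed = (1, 1), (0, 2)
    for s in _oracle_class_sets(layout22):
        assert not (shared in s and fixed in s)


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def test_monomorphic_block_is_k0(layout22):
    table = tabulate([np.zeros((0, 4), dtype=int)], layout22)
    assert table.entries == {(0, 0, 0, 0): 1}


def test_block_configuration_counts(layout22):
    # classes in lexicographic canonical order: (0,1), (0,2), (1,0), (1,1)
    block = np.array(
        [
            [1, 0, 0, 0],  # A-singleton -> class (1,0)
            [1, 0, 1, 0],  # shared -> (1,1)
            [0, 1, 0, 1],  # shared -> (1,1)
        ]
    )
    table = tabulate([block], layout22)
    assert table.entries == {(0, 0, 1, 2): 1}


def test_folding_merges_complementary_sites(layout22):
    """A (2,0) site and a (0,2) site land in the same folded class."""
    a = np.array([[1, 1, 0, 0]])
    b = np.array([[0, 0, 1, 1]])
    ta = tabulate([a], layout22)
    tb = tabulate([b], layout22)
    assert ta.entries == tb.entries == {(0, 1, 0, 0): 1}


def test_tabulate_invariances(layout22, rng):
    blocks = [rng.integers(0, 2, size=(rng.integers(0, 6), 4)) for _ in range(30)]
    base = tabulate(blocks, layout22)
    shuffled = list(blocks)
    rng.shuffle(shuffled)
    assert tabulate(shuffled, layout22).entries == base.entries
    # within-population genome relabeling (unphased data)
    relabeled = [b[:, [1, 0, 3, 2]] for b in blocks]
    assert tabulate(relabeled, layout22).entries == base.entries


def test_tabulate_drops_bad_sites_and_counts_them(layout22):
    block = np.array([[1, 0, 0, 0], [2, 0, 1, 0], [-1, 1, 0, 0]])
    table = tabulate([block], layout22)
    assert table.dropped_sites == 2
    assert table.entries == {(0, 0, 1, 0): 1}


def test_tabulate_rejects_wrong_sample_count(layout22):
    with pytest.raises(ValueError, match="block 0"):
        tabulate([np.zeros((1, 3), dtype=int)], layout22)


def test_lumping_caps_counts(layout22):
    block = np.array([[1, 0, 0, 0]] * 7)  # 7 A-singletons
    table = tabulate([block], layout22, LumpingSpec(4))
    assert table.entries == {(0, 0, LUMPED, 0): 1}


# ---------------------------------------------------------------------------
# Subsampling / cbSFS
# ---------------------------------------------------------------------------


def test_cbsfs_full_sample_equals_tabulate(layout22, rng):
    blocks = [rng.integers(0, 2, size=(3, 4)) for _ in range(20)]
    scheme = SubsamplingScheme.full_sample(layout22)
    assert (
        build_cbsfs(blocks, scheme, layout22).entries
        == tabulate(blocks, layout22).entries
    )


def test_all_subsets_counts():
    lay = SampleLayout((10, 10), block_length=100)  # five diploids per pop
    pairs = SubsamplingScheme.all_subsets(lay, 2)
    assert len(pairs.subsamples) == 45 * 45  # C(10,2)^2 genome pairs


def test_consecutive_diploids_cross_product():
    lay = SampleLayout((4, 6), block_length=100)
    scheme = SubsamplingScheme.consecutive_diploids(lay)
    assert len(scheme.subsamples) == 2 * 3
    assert scheme.sub_sizes == (2, 2)


def test_consecutive_diploids_single_pair_is_identity(layout22, rng):
    blocks = [rng.integers(0, 2, size=(2, 4)) for _ in range(15)]
    scheme = SubsamplingScheme.consecutive_diploids(layout22)
    assert len(scheme.subsamples) == 1
    assert (
        build_cbsfs(blocks, scheme, layout22).entries
        == tabulate(blocks, layout22).entries
    )


def test_cbsfs_total_blocks_scales_with_subsamples(rng):
    lay = SampleLayout((4, 4), block_length=100)
    blocks = [rng.integers(0, 2, size=(2, 8)) for _ in range(10)]
    scheme = SubsamplingScheme.consecutive_diploids(lay)
    table = build_cbsfs(blocks, scheme, lay)
    assert table.total_blocks == 10 * len(scheme.subsamples)
    assert table.layout.sizes == (2, 2)


def test_scheme_rejects_out_of_range_indices(layout22):
    scheme = SubsamplingScheme((((0, 5), (0, 1)),))
    with pytest.raises(ValueError, match="genome 5"):
        scheme.validate_against(layout22)


# ---------------------------------------------------------------------------
# Folding of tables
# ---------------------------------------------------------------------------


def test_fold_table_matches_direct_folded_tabulation(rng):
    pol = SampleLayout((2, 2), block_length=100, polarized=True)
    unpol = SampleLayout((2, 2), block_length=100, polarized=False)
    blocks = [rng.integers(0, 2, size=(4, 4)) for _ in range(25)]
    assert fold_table(tabulate(blocks, pol)).entries == tabulate(blocks, unpol).entries


def test_fold_table_is_idempotent(layout22, rng):
    blocks = [rng.integers(0, 2, size=(2, 4)) for _ in range(10)]
    table = tabulate(blocks, layout22)
    assert fold_table(table).entries == table.entries


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


@given(
    st.dictionaries(
        st.tuples(*[st.one_of(st.integers(0, 9), st.just(LUMPED))] * 4),
        st.integers(min_value=1, max_value=10**6),
        max_size=30,
    )
)
def test_table_round_trip(tmp_path_factory, entries):
    lay = SampleLayout((2, 2), block_length=2000, effective_length=1600)
    table = BsfsTable(layout=lay, lumping=LumpingSpec(9), entries=dict(entries))
    path = tmp_path_factory.mktemp("tables") / "t.tsv"
    write_table(table, path)
    back = read_table(path)
    assert back == table
    assert back.total_blocks == table.total_blocks


def test_empty_table_round_trip(tmp_path, layout22):
    table = BsfsTable(layout=layout22)
    write_table(table, tmp_path / "empty.tsv")
    back = read_table(tmp_path / "empty.tsv")
    assert back.total_blocks == 0
    assert back.layout == layout22


def test_read_table_reports_line_numbers(tmp_path, layout22):
    table = BsfsTable(layout=layout22, entries={(0, 0, 0, 0): 5})
    path = tmp_path / "t.tsv"
    write_table(table, path)
    bad = path.read_text().replace("0\t0\t0\t0\t5", "0\t0\t0\t5")
    path.write_text(bad)
    with pytest.raises(ValueError, match=":7"):
        read_table(path)


def test_read_table_refuses_foreign_files(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text("0\t0\t0\t0\t5\n")
    with pytest.raises(ValueError, match="not a blocklik"):
        read_table(p)


def test_all_diploid_subsets_counts():
    """Five diploids per population subsampled two diploids at a time:
    C(5,2)^2 = 100 subsamples, each of four genomes per population."""
    lay = SampleLayout((10, 10), block_length=100)
    scheme = SubsamplingScheme.all_diploid_subsets(lay, 2)
    assert len(scheme.subsamples) == 100
    assert scheme.sub_sizes == (4, 4)


def test_dump_summaries_writes_one_row_per_arg(tmp_path, rng):
    from blocklik.arg_sampler import dump_summaries
    from blocklik.classes import ClassIndex

    lay = SampleLayout((2, 2), block_length=100)
    mat = rng.exponential(size=(6, 4))
    path = tmp_path / "draws.tsv"
    dump_summaries(mat, ClassIndex(lay), path)
    back = np.loadtxt(path)
    assert np.allclose(back, mat)
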