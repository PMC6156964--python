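"""Sampling blockwise genealogies/ARGs and reducing them to branch-class
length vectors.

The composite likelihood never needs the genealogy itself — only, for each
sampled ancestral recombination graph (ARG), the *span-weighted average total
branch length per mutation class*

    t_{i,A} = (1/L) * sum_p w_p * t_{i,p}

over the S non-recombining marginal segments of the block (spans ``w_p``
summing to the block length ``L``).  Branch lengths are in units of
``4 * N_ref`` generations so that multiplying by ``theta_block`` gives the
Poisson mutation rate per class directly.

The coalescent-with-recombination backend is msprime; the reduction below is
the bespoke part.  Any backend exposing marginal trees with spans would do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import msprime
import numpy as np
import tskit

from .classes import ClassIndex, SampleLayout
from .demography import DemographicModel, to_scaled_units

__all__ = [
    "MarginalSegment",
    "ArgSummary",
    "SimulationError",
    "sample_args",
    "sample_class_matrix",
    "reduce_tree_sequence",
    "reduce_to_classes",
    "classify_topology",
    "congruent_fraction",
    "dump_summaries",
]


@dataclass
class MarginalSegment:
    """One non-recombining segment: physical span (bp) and the total branch
    length per mutation class (scaled time units)."""

    span: float
    class_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.class_lengths = np.asarray(self.class_lengths, dtype=float)
        if self.span < 1:
            raise ValueError("segment span must be >= 1 bp")
        if np.any(self.class_lengths < 0):
            raise ValueError("class lengths must be >= 0")


@dataclass
class ArgSummary:
    """Span-weighted average branch length per mutation class for one block.

    ``class_lengths[i]`` corresponds to ``index.classes[i]``.
    """

    class_lengths: np.ndarray
    index: ClassIndex
    num_segments: int = 1

    def __post_init__(self) -> None:
        self.class_lengths = np.asarray(self.class_lengths, dtype=float)


class SimulationError(RuntimeError):
    """Backend simulator failure; carries the scaled event list that caused
    it so the offending model point can be inspected."""

    def __init__(self, message: str, scaled_model=None):
        super().__init__(message)
        self.scaled_model = scaled_model


def _sample_sets(model: DemographicModel, layout: SampleLayout):
    """Layout sizes apply to the first X populations of the model, in order."""
    if layout.num_populations > len(model.populations):
        raise ValueError(
            "layout samples more populations than the model defines"
        )
    return [
        msprime.SampleSet(b, population=model.populations[x].name, ploidy=1)
        for x, b in enumerate(layout.sizes)
    ]


def _leaf_vectors(layout: SampleLayout) -> list[tuple[int, ...]]:
    """One-hot population membership per sample node (msprime orders sample
    nodes by sample set)."""
    X = layout.num_populations
    vecs = []
    for x, b in enumerate(layout.sizes):
        one = tuple(1 if i == x else 0 for i in range(X))
        vecs.extend([one] * b)
    return vecs


def reduce_tree_sequence(
    ts: tskit.TreeSequence,
    cindex: ClassIndex,
    leaf_vecs: list[tuple[int, ...]],
    time_scale: float,
) -> tuple[np.ndarray, int]:
    """Reduce one tree sequence to its class-length vector.

    Returns ``(t_A, num_segments)`` with ``t_A`` already span-averaged over
    the sequence length and converted to units of ``4 * N_ref`` generations
    via ``time_scale = 4 * N_ref``.
    """
    C = len(cindex)
    lookup = cindex.lookup
    total = np.zeros(C)
    L = ts.sequence_length
    nsegs = 0
    for tree in ts.trees():
        nsegs += 1
        tl = np.zeros(C)
        counts: dict[int, tuple[int, ...]] = {}
        for u in tree.nodes(order="postorder"):
            children = tree.children(u)
            if not children:
                vec = leaf_vecs[u]
            else:
                vec = tuple(
                    sum(col) for col in zip(*(counts[v] for v in children))
                )
            counts[u] = vec
            if tree.parent(u) != tskit.NULL:
                pos = lookup.get(vec)
                if pos is not None:
                    tl[pos] += tree.branch_length(u)
        # span/L is exactly 1.0 for a single marginal tree, which keeps the
        # rho=0 reduction bit-identical to the single-tree path
        total += (tree.span / L) * tl
    return total / time_scale, nsegs


def _single_tree_lengths(
    ts: tskit.TreeSequence,
    cindex: ClassIndex,
    leaf_vecs: list[tuple[int, ...]],
    time_scale: float,
) -> np.ndarray:
    """Single-genealogy reduction: no span weighting, one marginal tree.

    Deliberately separate from :func:`reduce_tree_sequence` — with
    ``rho_block = 0`` the two must agree draw-for-draw (the span-weighted
    average collapses to the one tree), which is a test contract of this
    module.
    """
    if ts.num_trees != 1:
        raise ValueError("single-tree reduction applied to a recombining block")
    tree = ts.first()
    tl = np.zeros(len(cindex))
    lookup = cindex.lookup
    counts: dict[int, tuple[int, ...]] = {}
    for u in tree.nodes(order="postorder"):
        children = tree.children(u)
        if not children:
            vec = leaf_vecs[u]
        else:
            vec = tuple(sum(col) for col in zip(*(counts[v] for v in children)))
        counts[u] = vec
        if tree.parent(u) != tskit.NULL:
            pos = lookup.get(vec)
            if pos is not None:
                tl[pos] += tree.branch_length(u)
    return tl / time_scale


def _replicates(
    model: DemographicModel,
    layout: SampleLayout,
    count: int,
    seed: int,
    single_tree: bool,
):
    rec = 0.0 if single_tree else model.recombination_rate
    # msprime seeds must be in [1, 2^32 - 1]
    ms_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**32 - 1)) + 1
    try:
        demography = model.to_msprime()
        reps = msprime.sim_ancestry(
            samples=_sample_sets(model, layout),
            demography=demography,
            sequence_length=layout.block_length,
            recombination_rate=rec,
            ploidy=2,
            discrete_genome=True,
            random_seed=ms_seed,
            num_replicates=count,
        )
    except Exception as err:  # pragma: no cover - backend failure path
        raise SimulationError(
            f"coalescent backend rejected the model: {err}",
            scaled_model=to_scaled_units(model, layout.block_length),
        ) from err
    return reps


def sample_args(
    model: DemographicModel,
    layout: SampleLayout,
    count: int,
    seed: int,
    *,
    single_tree: bool = False,
) -> Iterator[ArgSummary]:
    """Draw ``count`` independent blockwise ARGs and yield their reductions.

    With ``single_tree=True`` (or recombination rate zero) each draw is a
    single genealogy spanning the block, i.e. every summary has one marginal
    segment.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    cindex = ClassIndex(layout)
    leaf_vecs = _leaf_vectors(layout)
    time_scale = 4.0 * model.reference_size
    for ts in _replicates(model, layout, count, seed, single_tree):
        if single_tree:
            yield ArgSummary(
                _single_tree_lengths(ts, cindex, leaf_vecs, time_scale), cindex, 1
            )
        else:
            lengths, nsegs = reduce_tree_sequence(ts, cindex, leaf_vecs, time_scale)
            yield ArgSummary(lengths, cindex, nsegs)


def sample_class_matrix(
    model: DemographicModel,
    layout: SampleLayout,
    count: int,
    seed: int,
    *,
    single_tree: bool = False,
) -> np.ndarray:
    """Matrix of ``count`` class-length vectors, shape ``(count, C)`` — the
    bulk path used by the likelihood."""
    if count < 1:
        raise ValueError("count must be >= 1")
    cindex = ClassIndex(layout)
    leaf_vecs = _leaf_vectors(layout)
    time_scale = 4.0 * model.reference_size
    out = np.empty((count, len(cindex)))
    for i, ts in enumerate(_replicates(model, layout, count, seed, single_tree)):
        if single_tree:
            out[i] = _single_tree_lengths(ts, cindex, leaf_vecs, time_scale)
        else:
            out[i], _ = reduce_tree_sequence(ts, cindex, leaf_vecs, time_scale)
    return out


def reduce_to_classes(
    marginals: Sequence[MarginalSegment], layout: SampleLayout
) -> ArgSummary:
    """Exact span-weighted average of per-segment class lengths.

    Spans must sum to the block length; anything else is a hard error (a
    malformed ARG decomposition, not an infeasible model)."""
    if not marginals:
        raise ValueError("need at least one marginal segment")
    spans = np.array([m.span for m in marginals], dtype=float)
    if spans.sum() != layout.block_length:
        raise ValueError(
            f"segment spans sum to {spans.sum()}, expected block length "
            f"{layout.block_length}"
        )
    mat = np.vstack([m.class_lengths for m in marginals])
    lengths = spans @ mat / layout.block_length
    return ArgSummary(lengths, ClassIndex(layout), num_segments=len(marginals))


def classify_topology(summary: ArgSummary) -> set[tuple[int, ...]]:
    """The set of mutation classes with positive branch length — the block's
    'topology signature'.  For a two-population (2,2) sample without
    recombination, a genealogy is *incongruent* (can produce shared
    polymorphisms) iff the mixed-pair class (1,1) is in this set."""
    return {
        cls
        for cls, t in zip(summary.index.classes, summary.class_lengths)
        if t > 0
    }


def congruent_fraction(
    model: DemographicModel,
    layout: SampleLayout,
    count: int,
    seed: int,
) -> float:
    """Fraction of sampled genealogies with no branch ancestral to exactly
    one lineage from each of two populations (no shared-polymorphism class).
    """
    if layout.num_populations != 2:
        raise ValueError("congruence is defined for two-population samples")
    cindex = ClassIndex(layout)
    mixed = cindex.position((1, 1))
    draws = sample_class_matrix(model, layout, count, seed, single_tree=True)
    return float(np.mean(draws[:, mixed] == 0.0))


def dump_summaries(matrix: np.ndarray, cindex: ClassIndex, path) -> None:
    """Columnar text dump of raw draws: one row per ARG, one column per
    mutation class (debugging / convergence experiments)."""
    header = "\t".join("c" + "_".join(map(str, c)) for c in cindex.classes)
    np.savetxt(path, np.atleast_2d(matrix), delimiter="\t", header=header)
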