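"""Sample layouts and joint-SFS mutation-class combinatorics.

A *mutation class* (branch class) groups the branches of a genealogy by the
number of sampled lineages they are ancestral to in each population: for a
sample of ``b = (b_1, ..., b_X)`` genomes from ``X`` populations the unfolded
classes are the vectors ``(i_1, ..., i_X)`` with ``0 <= i_x <= b_x``, excluding
the all-zero vector and (for polarized data) the all-``b`` vector, giving
``prod(b_x + 1) - 2`` site types.  Without outgroup information the spectrum is
folded: each vector is merged with its complement ``(b_1 - i_1, ...)`` and the
lexicographically smaller member is the canonical representative.

The ordering produced here (lexicographic over canonical representatives) is
the single class-indexing convention used by every other module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "SampleLayout",
    "ClassIndex",
    "fold_vector",
    "num_site_types",
]


@dataclass(frozen=True)
class SampleLayout:
    """Shape of the sampled data: genomes per population and block geometry.

    Parameters
    ----------
    sizes
        ``b = (b_1, ..., b_X)``, number of sampled genomes (haploid sequences)
        per population.
    block_length
        Block length ``L`` in base pairs.
    effective_length
        Callable bases per block actually used for the mutation rate scaling
        (``theta_block``); defaults to ``block_length``.
    polarized
        True when an outgroup polarizes mutations (unfolded spectrum).
    """

    sizes: tuple[int, ...]
    block_length: int = 1
    effective_length: int | None = None
    polarized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(b) for b in self.sizes))
        if any(b < 1 for b in self.sizes):
            raise ValueError("each population must contribute at least one genome")
        if sum(self.sizes) < 2:
            raise ValueError("need at least two sampled genomes in total")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1 bp")
        if self.effective_length is None:
            object.__setattr__(self, "effective_length", self.block_length)
        if not 1 <= self.effective_length <= self.block_length:
            raise ValueError("effective_length must be in [1, block_length]")

    @property
    def num_populations(self) -> int:
        return len(self.sizes)

    @property
    def total_samples(self) -> int:
        return sum(self.sizes)

    def with_sizes(self, sizes: tuple[int, ...]) -> "SampleLayout":
        """Same block geometry with a different per-population sample size."""
        return SampleLayout(
            sizes=tuple(sizes),
            block_length=self.block_length,
            effective_length=self.effective_length,
            polarized=self.polarized,
        )


def fold_vector(vec: tuple[int, ...], sizes: tuple[int, ...]) -> tuple[int, ...]:
    """Canonical (folded) representative: the lexicographic min of a count
    vector and its complement."""
    comp = tuple(b - i for i, b in zip(vec, sizes))
    return min(vec, comp)


def _unfolded_vectors(sizes: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    zero = tuple(0 for _ in sizes)
    full = tuple(sizes)
    for vec in itertools.product(*(range(b + 1) for b in sizes)):
        if vec != zero and vec != full:
            yield vec


class ClassIndex:
    """Ordered mutation classes for a layout, with a lookup from any raw
    descendant-count vector to its class position.

    Attributes
    ----------
    classes
        Canonical class vectors in lexicographic order.
    lookup
        Maps every valid unfolded count vector (canonical or not) to the
        position of its class; folded layouts map complements to the same slot.
    """

    def __init__(self, layout: SampleLayout):
        self.layout = layout
        sizes = layout.sizes
        if layout.polarized:
            classes = sorted(_unfolded_vectors(sizes))
            lookup = {vec: pos for pos, vec in enumerate(classes)}
        else:
            classes = sorted({fold_vector(v, sizes) for v in _unfolded_vectors(sizes)})
            pos_of = {vec: pos for pos, vec in enumerate(classes)}
            lookup = {
                vec: pos_of[fold_vector(vec, sizes)] for vec in _unfolded_vectors(sizes)
            }
        self.classes: tuple[tuple[int, ...], ...] = tuple(classes)
        self.lookup: dict[tuple[int, ...], int] = lookup

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def position(self, vec: tuple[int, ...]) -> int:
        """Class position of a raw count vector (folding applied if needed)."""
        return self.lookup[tuple(vec)]


def num_site_types(layout: SampleLayout) -> int:
    """Number of distinguishable mutation classes under the layout.

    Unfolded: ``prod(b_x + 1) - 2``.  Folded: the count of canonical classes
    after complement-merging (there is no closed form the field routinely
    quotes, so we count).
    """
    return len(ClassIndex(layout))
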