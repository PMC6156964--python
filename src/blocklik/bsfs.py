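"""The blockwise site frequency spectrum (bSFS) and its combinatorics.

A block's *configuration* is the vector ``k = (k_1, ..., k_C)`` counting
mutations in each joint-SFS mutation class; the bSFS is the histogram of
configurations over blocks ("a histogram of histograms").  The monomorphic
configuration (all zeros) is ``k_0``.  With a *lumping* cap ``k_max``, any
per-class count exceeding the cap is pooled into a tail entry (rendered
``>k`` in serialized tables, :data:`LUMPED` internally), which closes the
configuration space so probabilities sum to one.  Without lumping
(``observed_only``) the table simply records whatever configurations occur.

The *composite* bSFS (cbSFS) pools the configurations of many subsamples of a
larger sample into one table at the subsample's layout — a projection that
makes arbitrarily large samples tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .classes import ClassIndex, SampleLayout, fold_vector, num_site_types

__all__ = [
    "LUMPED",
    "MutationClass",
    "BlockConfiguration",
    "LumpingSpec",
    "BsfsTable",
    "SubsamplingScheme",
    "num_site_types",
    "enumerate_configurations",
    "compatible_class_sets",
    "tabulate",
    "build_cbsfs",
    "fold_table",
    "read_table",
    "write_table",
]

logger = logging.getLogger(__name__)

#: Sentinel for a lumped (">k_max") entry inside a configuration vector.
LUMPED = -1

#: A mutation class is a per-population descendant-count vector.
MutationClass = tuple
#: A block configuration is a per-class count vector (``LUMPED`` = tail).
BlockConfiguration = tuple


@dataclass(frozen=True)
class LumpingSpec:
    """Per-class cap on mutation counts.

    ``mode="lumped"`` closes the configuration space with a ``>k_max`` tail
    entry per class; ``mode="observed_only"`` keeps exact counts and computes
    probabilities only for configurations present in the data.
    """

    k_max: int
    mode: str = "lumped"

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.mode not in ("lumped", "observed_only"):
            raise ValueError(f"unknown lumping mode {self.mode!r}")


@dataclass
class BsfsTable:
    """Histogram of block configurations.

    ``entries`` maps configuration tuples to block counts ``n_k``; the layout
    and (optional) lumping give the vectors meaning.
    """

    layout: SampleLayout
    lumping: LumpingSpec | None = None
    entries: dict[BlockConfiguration, int] = field(default_factory=dict)
    dropped_sites: int = field(default=0, compare=False)

    @property
    def total_blocks(self) -> int:
        return sum(self.entries.values())

    @property
    def num_configs(self) -> int:
        return len(self.entries)

    def add(self, config: BlockConfiguration, n: int = 1) -> None:
        self.entries[tuple(config)] = self.entries.get(tuple(config), 0) + n

    def validate(self) -> None:
        C = num_site_types(self.layout)
        for config, n in self.entries.items():
            if len(config) != C:
                raise ValueError(
                    f"configuration {config} has {len(config)} entries, "
                    f"expected {C} classes"
                )
            if n < 0:
                raise ValueError("negative block count")
            for k in config:
                if k == LUMPED:
                    if self.lumping is None or self.lumping.mode != "lumped":
                        raise ValueError(
                            "lumped entry present without an active lumping spec"
                        )
                elif k < 0:
                    raise ValueError(f"negative mutation count in {config}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(K, lumped_mask, n) — counts with tail entries zeroed out plus a
        boolean mask marking them, in deterministic (sorted) order."""
        configs = sorted(self.entries, key=_config_sort_key)
        K = np.array(configs, dtype=np.int64).reshape(len(configs), -1)
        mask = K == LUMPED
        K = np.where(mask, 0, K)
        n = np.array([self.entries[c] for c in configs], dtype=np.int64)
        return K, mask, n

    def configs_sorted(self) -> list[BlockConfiguration]:
        return sorted(self.entries, key=_config_sort_key)


def _config_sort_key(config: BlockConfiguration):
    # tail entries order after any exact count
    return tuple(np.inf if k == LUMPED else k for k in config)


# ---------------------------------------------------------------------------
# Configuration enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _reachable_class_sets(
    lineages: tuple[tuple[int, ...], ...], sizes: tuple[int, ...], polarized: bool
) -> frozenset[frozenset[tuple[int, ...]]]:
    """Class sets attainable by coalescing the given lineage count-vectors
    down to a root, excluding the root itself (memoized on the lineage
    multiset)."""
    if len(lineages) == 1:
        return frozenset([frozenset()])
    out: set[frozenset[tuple[int, ...]]] = set()
    seen_pairs: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for i, j in itertools.combinations(range(len(lineages)), 2):
        a, b = lineages[i], lineages[j]
        if (a, b) in seen_pairs:
            continue
        seen_pairs.add((a, b))
        merged = tuple(x + y for x, y in zip(a, b))
        rest = tuple(
            sorted(lineages[k] for k in range(len(lineages)) if k not in (i, j))
            + [merged]
        )
        sub = _reachable_class_sets(tuple(sorted(rest)), sizes, polarized)
        if len(lineages) == 2:
            out.update(sub)  # merged node is the root: not a branch class
        else:
            cls = merged if polarized else fold_vector(merged, sizes)
            out.update(s | {cls} for s in sub)
    return frozenset(out)


def compatible_class_sets(layout: SampleLayout) -> frozenset[frozenset]:
    """All mutation-class sets realisable on a single (non-recombining)
    genealogy of the sample, by exact enumeration of coalescent merge
    sequences.  Each returned set contains canonical class vectors."""
    X = layout.num_populations
    leaves = []
    for x, b in enumerate(layout.sizes):
        one = tuple(1 if i == x else 0 for i in range(X))
        leaves.extend([one] * b)
    leaf_classes = {
        v if layout.polarized else fold_vector(v, layout.sizes) for v in leaves
    }
    reach = _reachable_class_sets(
        tuple(sorted(leaves)), layout.sizes, layout.polarized
    )
    return frozenset(frozenset(leaf_classes) | s for s in reach)


_ENUM_LIMIT = 20_000_000


def enumerate_configurations(
    layout: SampleLayout,
    lumping: LumpingSpec,
    no_recombination: bool = False,
) -> list[BlockConfiguration]:
    """All lumped configurations: each class takes a value in
    ``{0, ..., k_max, >k_max}``.

    With ``no_recombination`` set, configurations whose positive classes
    cannot co-occur on any single genealogy (e.g. a shared polymorphism
    together with a fixed difference in a folded (2,2) sample) are excluded:
    they have probability zero without intra-block recombination.
    """
    if lumping.mode != "lumped":
        raise ValueError("enumeration requires a lumped configuration space")
    cindex = ClassIndex(layout)
    C = len(cindex)
    values = list(range(lumping.k_max + 1)) + [LUMPED]
    if len(values) ** C > _ENUM_LIMIT:
        raise ValueError(
            f"configuration space ({len(values)}^{C}) too large to enumerate"
        )
    if not no_recombination:
        return [cfg for cfg in itertools.product(values, repeat=C)]
    allowed_sets = compatible_class_sets(layout)
    classes = cindex.classes
    out = []
    for cfg in itertools.product(values, repeat=C):
        positive = frozenset(
            classes[c] for c, k in enumerate(cfg) if k != 0
        )
        if any(positive <= s for s in allowed_sets):
            out.append(cfg)
    return out


# ---------------------------------------------------------------------------
# Tabulation of per-block variant records
# ---------------------------------------------------------------------------


def _block_config(
    block: np.ndarray,
    layout: SampleLayout,
    cindex: ClassIndex,
    slices: list[slice],
    block_id,
) -> tuple[tuple[int, ...], int]:
    """Configuration of one block given its site-by-genome 0/1 allele matrix.

    Sites with missing (< 0) or non-biallelic (> 1) entries are dropped (and
    counted): they violate site-level completeness / infinite sites.  Sites
    invariant across the sample (all-0, or all-1 which folds to all-0 and for
    polarized data is a fixed substitution, not a polymorphism class) do not
    contribute.
    """
    block = np.asarray(block)
    if block.ndim != 2 or (block.size and block.shape[1] != layout.total_samples):
        raise ValueError(
            f"block {block_id!r}: expected matrix with {layout.total_samples} "
            f"genome columns, got shape {block.shape}"
        )
    counts = np.zeros(len(cindex), dtype=np.int64)
    dropped = 0
    for site in block:
        if site.min(initial=0) < 0 or site.max(initial=0) > 1:
            dropped += 1
            continue
        vec = tuple(int(site[s].sum()) for s in slices)
        pos = cindex.lookup.get(vec)
        if pos is not None:
            counts[pos] += 1
    return tuple(int(k) for k in counts), dropped


def _pop_slices(layout: SampleLayout) -> list[slice]:
    offsets = np.concatenate([[0], np.cumsum(layout.sizes)])
    return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]


def _apply_lumping(
    config: tuple[int, ...], lumping: LumpingSpec | None
) -> tuple[int, ...]:
    if lumping is None or lumping.mode != "lumped":
        return config
    return tuple(LUMPED if k > lumping.k_max else k for k in config)


def tabulate(
    blocks: Iterable[np.ndarray],
    layout: SampleLayout,
    lumping: LumpingSpec | None = None,
) -> BsfsTable:
    """Build the bSFS from per-block variant records.

    Each record is a ``(sites, genomes)`` 0/1 allele matrix (derived alleles
    if ``layout.polarized``, arbitrary orientation otherwise — folding makes
    the orientation irrelevant).  Blocks with no surviving variant count
    under the monomorphic configuration ``k_0``.
    """
    cindex = ClassIndex(layout)
    slices = _pop_slices(layout)
    table = BsfsTable(layout=layout, lumping=lumping)
    dropped = 0
    for i, block in enumerate(blocks):
        config, d = _block_config(block, layout, cindex, slices, i)
        dropped += d
        table.add(_apply_lumping(config, lumping))
    table.dropped_sites = dropped
    if dropped:
        logger.info("tabulate: dropped %d missing/multi-allelic sites", dropped)
    return table


@dataclass(frozen=True)
class SubsamplingScheme:
    """A list of subsamples for the cbSFS; each subsample picks
    ``b'_x`` within-population genome indices per population (all subsamples
    share the same per-population sizes)."""

    subsamples: tuple[tuple[tuple[int, ...], ...], ...]

    def __post_init__(self) -> None:
        if not self.subsamples:
            raise ValueError("scheme needs at least one subsample")
        shape = tuple(len(per_pop) for per_pop in self.subsamples[0])
        for sub in self.subsamples:
            if tuple(len(p) for p in sub) != shape:
                raise ValueError("all subsamples must have identical sizes")

    @property
    def sub_sizes(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.subsamples[0])

    def validate_against(self, layout: SampleLayout) -> None:
        if len(self.sub_sizes) != layout.num_populations:
            raise ValueError("scheme and layout population counts differ")
        for sub in self.subsamples:
            for x, per_pop in enumerate(sub):
                for idx in per_pop:
                    if not 0 <= idx < layout.sizes[x]:
                        raise ValueError(
                            f"subsample references genome {idx} of population "
                            f"{x}, which has only {layout.sizes[x]}"
                        )

    @classmethod
    def full_sample(cls, layout: SampleLayout) -> "SubsamplingScheme":
        return cls((tuple(tuple(range(b)) for b in layout.sizes),))

    @classmethod
    def consecutive_diploids(cls, layout: SampleLayout) -> "SubsamplingScheme":
        """One diploid (two consecutive genomes) per population, all
        cross-population combinations of such pairs."""
        per_pop_pairs = []
        for b in layout.sizes:
            if b % 2:
                raise ValueError("consecutive_diploids needs even sample sizes")
            per_pop_pairs.append([(i, i + 1) for i in range(0, b, 2)])
        return cls(tuple(itertools.product(*per_pop_pairs)))

    @classmethod
    def all_subsets(cls, layout: SampleLayout, per_pop: int) -> "SubsamplingScheme":
        """Every subset of ``per_pop`` genomes per population (cartesian
        across populations)."""
        choices = [
            list(itertools.combinations(range(b), per_pop)) for b in layout.sizes
        ]
        return cls(tuple(itertools.product(*choices)))

    @classmethod
    def all_diploid_subsets(
        cls, layout: SampleLayout, diploids_per_pop: int
    ) -> "SubsamplingScheme":
        """Every subset of ``diploids_per_pop`` diploid individuals (pairs of
        consecutive genomes) per population — e.g. five diploids per
        population subsampled two at a time gives C(5,2)^2 subsamples for two
        populations."""
        per_pop_choices = []
        for b in layout.sizes:
            if b % 2:
                raise ValueError("diploid subsampling needs even sample sizes")
            pairs = [(i, i + 1) for i in range(0, b, 2)]
            per_pop_choices.append(
                [
                    tuple(g for pair in combo for g in pair)
                    for combo in itertools.combinations(pairs, diploids_per_pop)
                ]
            )
        return cls(tuple(itertools.product(*per_pop_choices)))


def build_cbsfs(
    blocks: Iterable[np.ndarray],
    scheme: SubsamplingScheme,
    layout: SampleLayout,
    lumping: LumpingSpec | None = None,
) -> BsfsTable:
    """Pooled composite bSFS: each block contributes one configuration per
    subsample; the resulting table lives at the subsample layout and has
    ``total_blocks = blocks * subsamples``."""
    scheme.validate_against(layout)
    sub_layout = layout.with_sizes(scheme.sub_sizes)
    cindex = ClassIndex(sub_layout)
    slices = _pop_slices(sub_layout)
    offsets = np.concatenate([[0], np.cumsum(layout.sizes)])
    column_sets = [
        np.array(
            [int(offsets[x]) + i for x, per_pop in enumerate(sub) for i in per_pop],
            dtype=np.intp,
        )
        for sub in scheme.subsamples
    ]
    table = BsfsTable(layout=sub_layout, lumping=lumping)
    dropped = 0
    for bi, block in enumerate(blocks):
        block = np.asarray(block)
        if block.ndim != 2 or (block.size and block.shape[1] != layout.total_samples):
            raise ValueError(
                f"block {bi}: expected {layout.total_samples} genome columns, "
                f"got shape {block.shape}"
            )
        for cols in column_sets:
            sub_block = block[:, cols] if block.size else block.reshape(0, len(cols))
            config, d = _block_config(sub_block, sub_layout, cindex, slices, bi)
            dropped += d
            table.add(_apply_lumping(config, lumping))
    table.dropped_sites = dropped
    return table


def fold_table(table: BsfsTable) -> BsfsTable:
    """Fold a table (merge complement classes).  Folding an already-folded
    table is the identity."""
    if not table.layout.polarized:
        return BsfsTable(
            layout=table.layout,
            lumping=table.lumping,
            entries=dict(table.entries),
            dropped_sites=table.dropped_sites,
        )
    if table.lumping is not None and table.lumping.mode == "lumped":
        raise ValueError("cannot fold a lumped table: tail entries do not add")
    src = ClassIndex(table.layout)
    folded_layout = SampleLayout(
        sizes=table.layout.sizes,
        block_length=table.layout.block_length,
        effective_length=table.layout.effective_length,
        polarized=False,
    )
    dst = ClassIndex(folded_layout)
    mapping = [dst.lookup[cls] for cls in src.classes]
    out = BsfsTable(layout=folded_layout, lumping=table.lumping)
    for config, n in table.entries.items():
        merged = [0] * len(dst)
        for c, k in enumerate(config):
            merged[mapping[c]] += k
        out.add(tuple(merged), n)
    out.dropped_sites = table.dropped_sites
    return out


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

_MAGIC = "#blocklik-bsfs\tv1"


def write_table(table: BsfsTable, path) -> None:
    """Tab-separated text: a commented header with layout and lumping, then
    one line per configuration (class counts, ``>k`` for tail entries, final
    column ``n_k``)."""
    table.validate()
    lay = table.layout
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"#sizes\t{','.join(map(str, lay.sizes))}\n")
        fh.write(f"#block_length\t{lay.block_length}\n")
        fh.write(f"#effective_length\t{lay.effective_length}\n")
        fh.write(f"#polarized\t{int(lay.polarized)}\n")
        if table.lumping is None:
            fh.write("#lumping\tnone\n")
        else:
            fh.write(f"#lumping\t{table.lumping.mode}\t{table.lumping.k_max}\n")
        for config in table.configs_sorted():
            cells = [
                f">{table.lumping.k_max}" if k == LUMPED else str(k) for k in config
            ]
            fh.write("\t".join(cells + [str(table.entries[config])]) + "\n")


def read_table(path) -> BsfsTable:
    """Inverse of :func:`write_table`; malformed lines raise with their line
    number."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a blocklik bSFS table")
    header: dict[str, list[str]] = {}
    body_start = 1
    for ln, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            body_start = ln
            break
        key, *vals = line[1:].split("\t")
        header[key] = vals
        body_start = ln + 1
    try:
        layout = SampleLayout(
            sizes=tuple(int(s) for s in header["sizes"][0].split(",")),
            block_length=int(header["block_length"][0]),
            effective_length=int(header["effective_length"][0]),
            polarized=bool(int(header["polarized"][0])),
        )
        lump_spec = header["lumping"]
    except (KeyError, IndexError, ValueError) as err:
        raise ValueError(f"{path}: malformed header: {err}") from err
    if lump_spec[0] == "none":
        lumping = None
    else:
        lumping = LumpingSpec(mode=lump_spec[0], k_max=int(lump_spec[1]))
    table = BsfsTable(layout=layout, lumping=lumping)
    C = num_site_types(layout)
    for ln, line in enumerate(lines[body_start - 1 :], start=body_start):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != C + 1:
            raise ValueError(
                f"{path}:{ln}: expected {C} class counts + n_k, got "
                f"{len(cells)} fields"
            )
        try:
            config = tuple(
                LUMPED if c.startswith(">") else int(c) for c in cells[:-1]
            )
            n = int(cells[-1])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: {err}") from err
        table.add(config, n)
    table.validate()
    return table
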