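"""Building bSFS tables from a VCF plus a BED callable-sites mask.

Blocks are half-open, 0-based ``[k*L, (k+1)*L)`` windows on each contig.  A
block is retained iff at least ``q * L`` of its bases are callable (the BED
mask is taken to be the intersection over individuals), and exactly the
*first* ``floor(q * L)`` callable bases are used, so every retained block has
the same effective length — which is what the block mutation rate
``theta_block`` is scaled by.

Sites with any missing genotype are dropped from their block (site-level
completeness); multi-allelic and non-SNP records violate the infinite-sites
assumption and are dropped too; all drops are counted on the returned table.
Polarized tabulation requires the ancestral allele in the ``AA`` INFO field
and refuses to guess: sites whose ``AA`` matches neither allele are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from cyvcf2 import VCF

from .bsfs import BsfsTable, LumpingSpec, tabulate
from .classes import SampleLayout

__all__ = ["read_bed_mask", "blocks_from_vcf", "tabulate_vcf", "vcf_layout"]

logger = logging.getLogger(__name__)


def read_bed_mask(path) -> dict[str, np.ndarray]:
    """BED3 -> {contig: (n, 2) array of half-open 0-based intervals, sorted}."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from err
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            raw.setdefault(fields[0], []).append((start, end))
    return {
        contig: np.array(sorted(ivals), dtype=np.int64)
        for contig, ivals in raw.items()
    }


def _callable_positions(intervals: np.ndarray, start: int, end: int) -> np.ndarray:
    """Sorted callable positions of the mask clipped to [start, end)."""
    lo = np.clip(intervals[:, 0], start, end)
    hi = np.clip(intervals[:, 1], start, end)
    parts = [np.arange(a, b) for a, b in zip(lo, hi) if b > a]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def vcf_layout(
    populations: dict[str, list[str]],
    block_length: int,
    min_callable_fraction: float = 0.8,
    polarized: bool = False,
    ploidy: int = 2,
) -> SampleLayout:
    """Layout implied by a population -> sample-names mapping (each sample
    contributes ``ploidy`` genomes)."""
    return SampleLayout(
        sizes=tuple(ploidy * len(names) for names in populations.values()),
        block_length=block_length,
        effective_length=int(min_callable_fraction * block_length),
        polarized=polarized,
    )


@dataclass
class _BlockBucket:
    used: np.ndarray  # sorted used positions (0-based)
    sites: list[np.ndarray]


def blocks_from_vcf(
    vcf_path,
    bed_path,
    populations: dict[str, list[str]],
    block_length: int,
    min_callable_fraction: float = 0.8,
    polarized: bool = False,
) -> Iterator[np.ndarray]:
    """Yield per-block 0/1 genome matrices for every retained block.

    The VCF is streamed once (no index needed); variants are bucketed into
    blocks by position, restricted to each block's used callable bases.
    Diploid genotypes contribute two genome columns per sample, ordered by
    population then sample.
    """
    mask = read_bed_mask(bed_path)
    eff = int(min_callable_fraction * block_length)
    if eff < 1:
        raise ValueError("min_callable_fraction * block_length must be >= 1")

    vcf = VCF(str(vcf_path))
    sample_pos = {name: i for i, name in enumerate(vcf.samples)}
    col_samples: list[int] = []
    for pop, names in populations.items():
        for name in names:
            if name not in sample_pos:
                raise ValueError(f"sample {name!r} (population {pop}) not in VCF")
            col_samples.append(sample_pos[name])
    n_genomes = 2 * len(col_samples)

    buckets: dict[tuple[str, int], _BlockBucket] = {}
    order: list[tuple[str, int]] = []
    for contig, intervals in mask.items():
        last = int(intervals[:, 1].max())
        for k in range(0, (last + block_length - 1) // block_length):
            start = k * block_length
            pos = _callable_positions(intervals, start, start + block_length)
            if len(pos) >= eff:
                key = (contig, k)
                buckets[key] = _BlockBucket(used=pos[:eff], sites=[])
                order.append(key)
    for v in vcf:
        p0 = v.POS - 1  # VCF is 1-based
        key = (v.CHROM, p0 // block_length)
        bucket = buckets.get(key)
        if bucket is None:
            continue
        i = np.searchsorted(bucket.used, p0)
        if i >= len(bucket.used) or bucket.used[i] != p0:
            continue  # outside the used callable bases
        if not v.ALT:
            continue  # monomorphic record
        if len(v.ALT) > 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            # multi-allelic / non-SNP: emit an invalid row so the tabulator
            # drops and counts it
            bucket.sites.append(np.full(n_genomes, -1, dtype=np.int8))
            continue
        gts = v.genotypes
        alleles = np.empty(n_genomes, dtype=np.int8)
        for j, s in enumerate(col_samples):
            a1, a2 = gts[s][0], gts[s][1]
            alleles[2 * j] = a1 if a1 >= 0 else -1
            alleles[2 * j + 1] = a2 if a2 >= 0 else -1
        if polarized and alleles.min() >= 0:
            aa = v.INFO.get("AA")
            if aa is None:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: polarized tabulation requires the AA "
                    "INFO field"
                )
            aa = str(aa).upper()
            if aa == v.REF.upper():
                pass
            elif aa == v.ALT[0].upper():
                alleles = 1 - alleles
            else:
                alleles = np.full(n_genomes, -1, dtype=np.int8)
        bucket.sites.append(alleles)
    for key in order:
        b = buckets[key]
        yield (
            np.vstack(b.sites)
            if b.sites
            else np.zeros((0, n_genomes), dtype=np.int8)
        )


def tabulate_vcf(
    vcf_path,
    bed_path,
    populations: dict[str, list[str]],
    block_length: int,
    min_callable_fraction: float = 0.8,
    polarized: bool = False,
    lumping: LumpingSpec | None = None,
) -> BsfsTable:
    """End-to-end VCF + BED -> bSFS table."""
    layout = vcf_layout(populations, block_length, min_callable_fraction, polarized)
    blocks = blocks_from_vcf(
        vcf_path,
        bed_path,
        populations,
        block_length,
        min_callable_fraction,
        polarized,
    )
    return tabulate(blocks, layout, lumping)
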