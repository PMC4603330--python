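"""Superblocks: sets of target blocks that overlap in the reference genome.

After one or more whole-genome duplications, several regions of a target
genome descend from one ancestral region and therefore project onto the
same stretch of a reference genome.  A *superblock* is a set of B >= 2
syntenic blocks whose reference footprints overlap each other by at least
T genes; B is the superblock's *multiplicity*.  The empirical distribution
f(B) of multiplicities over all superblocks is the raw signal from which
the WGD signature (the exponential tail decay rate c) is extracted.

Overlap is formalised as connectivity: per reference chromosome, blocks
are nodes and any pair overlapping by >= T genes is an edge; connected
components of size >= 2 are superblocks.  Connectivity makes the union
span contiguous in coverage and is independent of input order.  Overlap is
strand-agnostic — only the reference footprint matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .synteny import SyntenicBlock

__all__ = [
    "Superblock",
    "OverlapParams",
    "MultiplicityDistribution",
    "overlap_genes",
    "build_superblocks",
    "multiplicity_distribution",
]


@dataclass(frozen=True)
class Superblock:
    """A connected set of >= 2 blocks overlapping on one reference chromosome."""

    reference_chromosome: str
    member_blocks: frozenset[str]
    multiplicity_B: int
    reference_union_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.multiplicity_B < 2:
            raise ValueError("superblock multiplicity must be >= 2")
        if self.multiplicity_B != len(self.member_blocks):
            raise ValueError("multiplicity must equal member count")


@dataclass(frozen=True)
class OverlapParams:
    """T = minimum reference overlap, in genes, for two blocks to connect.

    The analysis sweeps T in {5, 10}: requiring much more than ten genes
    suppresses high multiplicities, while much less than five produces
    artifactually high ones.  Values outside [5, 10] are allowed but
    trigger a warning.
    """

    min_overlap_genes: int = 5

    def __post_init__(self) -> None:
        if self.min_overlap_genes < 1:
            raise ValueError("min_overlap_genes must be >= 1")
        if not 5 <= self.min_overlap_genes <= 10:
            warnings.warn(
                f"overlap threshold T={self.min_overlap_genes} is outside the "
                "recommended [5, 10] range",
                stacklevel=3,
            )


@dataclass
class MultiplicityDistribution:
    """Empirical f(B): count of superblocks per multiplicity B >= 2.

    Missing keys mean f(B) = 0.  Counts are raw (not proportions); the
    fitted decay rate c is invariant to positive rescaling so the choice
    is observationally neutral.  ``provenance`` records the comparison the
    distribution came from, conventionally (target_id, reference_id, minL, T).
    """

    counts: dict[int, int] = field(default_factory=dict)
    provenance: tuple = ()

    def __post_init__(self) -> None:
        for b, n in self.counts.items():
            if b < 2 or n < 0:
                raise ValueError(f"invalid multiplicity entry B={b}, count={n}")

    def total_superblocks(self) -> int:
        return sum(self.counts.values())


def overlap_genes(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Number of genes shared by two inclusive ordinal intervals."""
    if span_a[0] > span_a[1] or span_b[0] > span_b[1]:
        raise ValueError("interval lower bound exceeds upper bound")
    return max(0, min(span_a[1], span_b[1]) - max(span_a[0], span_b[0]) + 1)


def build_superblocks(
    blocks: Sequence[SyntenicBlock], params: OverlapParams = OverlapParams()
) -> list[Superblock]:
    """Group blocks into superblocks by >= T-gene reference overlap.

    Per reference chromosome, builds the pairwise overlap graph and takes
    connected components; components of size 1 produce nothing.  Output is
    sorted by (reference chromosome, union span lower bound).
    """
    T = params.min_overlap_genes
    by_chrom: dict[str, list[SyntenicBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.reference_chromosome, []).append(b)
    out: list[Superblock] = []
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda b: (b.reference_span, b.block_id))
        g = nx.Graph()
        g.add_nodes_from(b.block_id for b in group)
        for i, bi in enumerate(group):
            # sorted by span lo: once lo_j passes hi_i - T + 1 no later
            # block can overlap bi by >= T genes
            for bj in group[i + 1 :]:
                if bj.reference_span[0] > bi.reference_span[1] - T + 1:
                    break
                if overlap_genes(bi.reference_span, bj.reference_span) >= T:
                    g.add_edge(bi.block_id, bj.block_id)
        spans = {b.block_id: b.reference_span for b in group}
        for comp in nx.connected_components(g):
            if len(comp) < 2:
                continue
            lo = min(spans[bid][0] for bid in comp)
            hi = max(spans[bid][1] for bid in comp)
            out.append(
                Superblock(
                    reference_chromosome=chrom,
                    member_blocks=frozenset(comp),
                    multiplicity_B=len(comp),
                    reference_union_span=(lo, hi),
                )
            )
    out.sort(key=lambda s: (s.reference_chromosome, s.reference_union_span))
    return out


def multiplicity_distribution(
    superblocks: Iterable[Superblock], provenance: tuple = ()
) -> MultiplicityDistribution:
    """Tabulate f(B) over superblocks; empty input gives empty counts."""
    counts: dict[int, int] = {}
    for s in superblocks:
        counts[s.multiplicity_B] = counts.get(s.multiplicity_B, 0) + 1
    return MultiplicityDistribution(counts=dict(sorted(counts.items())),
                                    provenance=provenance)
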