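"""Panel design enumeration, pairwise c comparisons, and genome ranking.

The full design crosses every ordered (target, reference) genome pair
with a sweep of block-validation thresholds (minL) and tail cutoffs
(B_min) — for 15 genomes with three values of each that is 210 ordered
pairs and 1890 cells.  For each unordered pair of target genomes {G, H}
and each shared condition (a reference genome distinct from both, one
minL, one cutoff, and the overlap threshold T when swept), the fitted
decay rates are compared head-to-head; with 15 genomes and no missing
fits every pair gets 13 x 3 x 3 = 117 comparisons, 39 per fixed minL.

Genomes are then ranked by dominance: G's score is the number of
opponents H it beats in the majority of their shared comparisons.  Rank 1
is the genome with the largest c profile — the least persistent
multiplicity tail, i.e. the least WGD signal.  Exact ties in c count for
neither side; cells with a missing c are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ComparisonCell",
    "WinMatrix",
    "GenomeRanking",
    "RankEntry",
    "enumerate_cells",
    "pairwise_wins",
    "rank_genomes",
]


@dataclass(frozen=True)
class ComparisonCell:
    """One cell of the design: a (target, reference, minL, B_min[, T]) fit.

    ``c`` is the fitted decay rate, or None when the fit was undefined
    (too few positive multiplicities in that cell).
    """

    target_id: str
    reference_id: str
    min_anchors: int  # minL
    tail_cutoff: int  # B_min
    overlap_T: int = 5
    c: float | None = None

    def __post_init__(self) -> None:
        if self.target_id == self.reference_id:
            raise ValueError("target and reference must differ")

    @property
    def condition(self) -> tuple:
        """The comparison key shared by both targets of a pair."""
        return (self.reference_id, self.min_anchors, self.tail_cutoff, self.overlap_T)


@dataclass
class WinMatrix:
    """Pairwise win counts over shared comparison cells.

    ``wins[(G, H)]`` counts cells where c(G) > c(H); ``comparable[(G, H)]``
    (symmetric) counts cells where both were defined.  Ties contribute to
    ``comparable`` only, so wins(G,H) + wins(H,G) <= comparable(G,H).
    """

    genomes: list[str]
    wins: dict[tuple[str, str], int] = field(default_factory=dict)
    comparable: dict[tuple[str, str], int] = field(default_factory=dict)

    def total_wins(self, genome: str) -> int:
        return sum(n for (g, _), n in self.wins.items() if g == genome)


@dataclass(frozen=True)
class RankEntry:
    rank: int
    genome_id: str
    dominance: int
    total_wins: int


@dataclass
class GenomeRanking:
    """Genomes ordered by descending dominance; rank 1 = largest c profile."""

    entries: list[RankEntry]

    def order(self) -> list[str]:
        return [e.genome_id for e in self.entries]


def enumerate_cells(
    genome_ids: Sequence[str],
    minl_values: Sequence[int] = (3, 4, 5),
    cutoff_values: Sequence[int] = (2, 3, 4),
    overlap_values: Sequence[int] = (5,),
) -> list[tuple[str, str, int, int, int]]:
    """All (target, reference, minL, B_min, T) cell keys, in deterministic order.

    Every ordered pair of distinct genomes is crossed with the parameter
    sweeps; duplicate genome ids are a hard error.
    """
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome id in panel")
    if len(genome_ids) < 2:
        raise ValueError("panel needs at least two genomes")
    return [
        (t, r, ml, bm, T)
        for t in genome_ids
        for r in genome_ids
        if t != r
        for ml in minl_values
        for bm in cutoff_values
        for T in overlap_values
    ]


def pairwise_wins(cells: Iterable[ComparisonCell]) -> WinMatrix:
    """Count head-to-head c wins between every pair of target genomes.

    For an unordered pair {G, H}, the comparisons run over conditions
    (reference, minL, B_min, T) present for both targets with the
    reference distinct from G and H.  c(G) > c(H) increments wins(G, H);
    exact ties and conditions where either c is missing count for neither.
    """
    by_target: dict[str, dict[tuple, float | None]] = {}
    genomes: list[str] = []
    for cell in cells:
        if cell.target_id not in by_target:
            by_target[cell.target_id] = {}
            genomes.append(cell.target_id)
        by_target[cell.target_id][cell.condition] = cell.c
    matrix = WinMatrix(genomes=genomes)
    for g, h in itertools.combinations(genomes, 2):
        w_gh = w_hg = comp = 0
        for cond, cg in by_target[g].items():
            if cond[0] in (g, h):
                continue
            if cond not in by_target[h]:
                continue
            ch = by_target[h][cond]
            if cg is None or ch is None:
                continue
            comp += 1
            if cg > ch:
                w_gh += 1
            elif ch > cg:
                w_hg += 1
        matrix.wins[(g, h)] = w_gh
        matrix.wins[(h, g)] = w_hg
        matrix.comparable[(g, h)] = comp
        matrix.comparable[(h, g)] = comp
    return matrix


def rank_genomes(matrix: WinMatrix) -> GenomeRanking:
    """Rank genomes by head-to-head dominance.

    Dominance of G = number of opponents H with wins(G, H) > wins(H, G).
    Sorting is by descending dominance, then descending total wins, then
    genome id; ranks are 1..n contiguous.
    """
    dominance: dict[str, int] = {g: 0 for g in matrix.genomes}
    for g, h in itertools.combinations(matrix.genomes, 2):
        w_gh = matrix.wins.get((g, h), 0)
        w_hg = matrix.wins.get((h, g), 0)
        if w_gh > w_hg:
            dominance[g] += 1
        elif w_hg > w_gh:
            dominance[h] += 1
    ordered = sorted(
        matrix.genomes,
        key=lambda g: (-dominance[g], -matrix.total_wins(g), g),
    )
    entries = [
        RankEntry(rank=i, genome_id=g, dominance=dominance[g],
                  total_wins=matrix.total_wins(g))
        for i, g in enumerate(ordered, 1)
    ]
    return GenomeRanking(entries=entries)
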