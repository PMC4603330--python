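"""Chaining collinear homolog anchors into syntenic blocks.

A syntenic block is a run of homologous gene pairs in conserved order and
proximity between a target and a reference chromosome.  The chainer here
follows the DAGchainer recipe in simplified form: on each chromosome pair,
anchors (dots of the comparative dot-plot) are chained by dynamic
programming under a strict-monotonicity and bounded-gap contract, the
highest-scoring chain is extracted, its anchors are removed, and the
process repeats until the best remaining chain falls below ``minL`` — the
minimum number of homologs required to validate a block.

This is a documented stand-in so the whole pipeline is testable without an
external synteny server; blocks computed by external tools can be imported
through :func:`wgdsig.io.read_dagchainer_blocks` instead, and both paths
produce the same :class:`SyntenicBlock` type.

Scoring is by anchor count with summed percent similarity as tie-break;
all remaining ties are resolved by fixed lexicographic rules so block
extraction is deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GenomeAnnotation, HomologPair

__all__ = [
    "AnchorPair",
    "SyntenicBlock",
    "ChainingParams",
    "find_syntenic_blocks",
    "filter_blocks",
]


@dataclass(frozen=True)
class AnchorPair:
    """One homologous gene pair in ordinal coordinates (a dot-plot dot)."""

    target_ordinal: int
    reference_ordinal: int
    similarity: float

    def __post_init__(self) -> None:
        if self.target_ordinal < 1 or self.reference_ordinal < 1:
            raise ValueError("ordinals are 1-based and must be >= 1")


@dataclass(frozen=True)
class SyntenicBlock:
    """A chained run of anchors between one target and one reference chromosome.

    Anchors are strictly increasing in target ordinal; reference ordinals
    are strictly increasing for ``parallel`` blocks and strictly decreasing
    for ``antiparallel`` ones.  Spans are inclusive ordinal intervals equal
    to the min/max anchor ordinals on each genome.
    """

    block_id: str
    target_chromosome: str
    reference_chromosome: str
    anchors: tuple[AnchorPair, ...]
    orientation: str  # "parallel" | "antiparallel"
    target_span: tuple[int, int]
    reference_span: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def validate(self, max_gap: int | None = None) -> None:
        """Assert the monotonicity / span / gap invariants; raise on violation."""
        ts = [a.target_ordinal for a in self.anchors]
        rs = [a.reference_ordinal for a in self.anchors]
        if self.target_span != (min(ts), max(ts)):
            raise ValueError(f"{self.block_id}: target span mismatch")
        if self.reference_span != (min(rs), max(rs)):
            raise ValueError(f"{self.block_id}: reference span mismatch")
        sign = 1 if self.orientation == "parallel" else -1
        for (t0, r0), (t1, r1) in zip(zip(ts, rs), zip(ts[1:], rs[1:])):
            if t1 <= t0:
                raise ValueError(f"{self.block_id}: target ordinals not increasing")
            if sign * (r1 - r0) <= 0:
                raise ValueError(f"{self.block_id}: reference ordinals not monotone")
            if max_gap is not None and (
                t1 - t0 > max_gap or abs(r1 - r0) > max_gap
            ):
                raise ValueError(f"{self.block_id}: gap exceeds max_gap")


@dataclass(frozen=True)
class ChainingParams:
    """minL = minimum anchors to validate a block; max_gap = maximum ordinal
    gap (in genes, on both genomes) between consecutive anchors of a chain."""

    min_anchors: int = 5
    max_gap: int = 20

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors (minL) must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


def _block_from_anchors(
    block_id: str, tchr: str, rchr: str, anchors: Sequence[AnchorPair]
) -> SyntenicBlock:
    ts = [a.target_ordinal for a in anchors]
    rs = [a.reference_ordinal for a in anchors]
    if len(anchors) >= 2 and rs[1] < rs[0]:
        orientation = "antiparallel"
    else:
        orientation = "parallel"
    return SyntenicBlock(
        block_id=block_id,
        target_chromosome=tchr,
        reference_chromosome=rchr,
        anchors=tuple(anchors),
        orientation=orientation,
        target_span=(min(ts), max(ts)),
        reference_span=(min(rs), max(rs)),
    )


def _best_chain(
    anchors: list[tuple[int, int, float]], max_gap: int, antiparallel: bool
) -> tuple[int, float, list[int]]:
    """Highest-scoring monotone gap-bounded chain over ``anchors``.

    Returns (length, summed similarity, indices into ``anchors``).  Scoring
    maximises (length, similarity sum); remaining ties are broken towards
    the chain ending (and extending through) the smallest (t, r) anchors,
    which makes extraction deterministic.
    """
    n = len(anchors)
    if n == 0:
        return 0, 0.0, []
    # work in (t, r') with r' = -r for antiparallel chains, so both
    # orientations share the "strictly increasing, gap <= max_gap" rule
    pts = [
        (t, -r if antiparallel else r, s, i)
        for i, (t, r, s) in enumerate(anchors)
    ]
    pts.sort(key=lambda p: (p[0], p[1]))
    length = [1] * n
    simsum = [p[2] for p in pts]
    pred = [-1] * n
    lo = 0
    for v in range(n):
        tv, rv = pts[v][0], pts[v][1]
        while pts[lo][0] < tv - max_gap:
            lo += 1
        best_key = None
        best_u = -1
        for u in range(lo, v):
            tu, ru = pts[u][0], pts[u][1]
            if tu == tv:
                continue
            dr = rv - ru
            if dr <= 0 or dr > max_gap:
                continue
            key = (length[u], simsum[u], -tu, -ru)
            if best_key is None or key > best_key:
                best_key = key
                best_u = u
        if best_u >= 0:
            length[v] = length[best_u] + 1
            simsum[v] = simsum[best_u] + pts[v][2]
            pred[v] = best_u
    end = max(range(n), key=lambda v: (length[v], simsum[v], -pts[v][0], -pts[v][1]))
    chain: list[int] = []
    v = end
    while v >= 0:
        chain.append(pts[v][3])
        v = pred[v]
    chain.reverse()
    return length[end], simsum[end], chain


def extract_chains(
    anchors: Sequence[tuple[int, int, float]],
    min_anchors: int,
    max_gap: int,
) -> list[tuple[list[tuple[int, int, float]], str]]:
    """Iteratively extract best-first chains from one chromosome pair.

    Each round the best parallel and best antiparallel chain over the
    remaining anchors compete; the winner (by anchor count, then summed
    similarity, parallel preferred on exact ties) is extracted and its
    anchors removed.  Extraction stops when the best chain has fewer than
    ``min_anchors`` anchors — removal never lengthens later chains, so
    every discarded chain would be discarded anyway.
    """
    remaining = sorted(anchors, key=lambda a: (a[0], a[1]))
    out: list[tuple[list[tuple[int, int, float]], str]] = []
    while remaining:
        lp, sp, chain_p = _best_chain(remaining, max_gap, antiparallel=False)
        la, sa, chain_a = _best_chain(remaining, max_gap, antiparallel=True)
        if (lp, sp) >= (la, sa):
            score, chain, orient = (lp, sp), chain_p, "parallel"
        else:
            score, chain, orient = (la, sa), chain_a, "antiparallel"
        if score[0] < min_anchors:
            break
        picked = [remaining[i] for i in chain]
        out.append((picked, orient))
        drop = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in drop]
    return out


def find_syntenic_blocks(
    pairs: Iterable[HomologPair],
    target: GenomeAnnotation,
    reference: GenomeAnnotation,
    params: ChainingParams = ChainingParams(),
) -> list[SyntenicBlock]:
    """Chain homolog pairs into syntenic blocks.

    Anchors are grouped per (target chromosome, reference chromosome) and
    chained independently in each group.  Block ids are
    ``"<tchr>_<rchr>_<k>"`` with ``k`` counting extraction order within the
    group; groups are processed in annotation chromosome order, so output
    is deterministic.  A homolog naming a gene absent from its annotation
    is a hard error.
    """
    groups: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    for p in pairs:
        tg = target.gene(p.target_gene)
        rg = reference.gene(p.reference_gene)
        groups.setdefault((tg.chromosome, rg.chromosome), []).append(
            (tg.ordinal, rg.ordinal, p.similarity)
        )
    t_order = {c: i for i, c in enumerate(target.chromosomes)}
    r_order = {c: i for i, c in enumerate(reference.chromosomes)}
    blocks: list[SyntenicBlock] = []
    for tchr, rchr in sorted(groups, key=lambda k: (t_order[k[0]], r_order[k[1]])):
        chains = extract_chains(groups[(tchr, rchr)], params.min_anchors, params.max_gap)
        for k, (chain, orient) in enumerate(chains, 1):
            anchors = [AnchorPair(t, r, s) for t, r, s in chain]
            block = _block_from_anchors(f"{tchr}_{rchr}_{k}", tchr, rchr, anchors)
            assert block.orientation == orient
            blocks.append(block)
    return blocks


def filter_blocks(
    blocks: Iterable[SyntenicBlock], min_anchors: int
) -> list[SyntenicBlock]:
    """Re-threshold blocks by anchor count (minL), preserving order.

    Useful for imported blocks, and for sweeping minL without re-chaining:
    best-first extraction yields blocks in non-increasing anchor-count
    order, so filtering blocks chained at a lower minL reproduces the
    blocks that chaining at the higher minL would return.
    """
    return [b for b in blocks if b.n_anchors >= min_anchors]
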