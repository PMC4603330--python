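"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the slow, obviously-correct route: exhaustive
chain enumeration instead of dynamic programming, and an explicit pairwise
overlap matrix with transitive closure instead of incremental graph
construction.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from wgdsig.synteny import AnchorPair, SyntenicBlock


def best_chain_bruteforce(
    anchors: list[tuple[int, int, float]], max_gap: int
) -> tuple[int, float, list[int]]:
    """Exhaustive DFS over all monotone gap-bounded chains (<= ~12 anchors)."""
    best: tuple[tuple[int, float], list[int]] = ((0, 0.0), [])

    def rec(chain: list[int], orient: int | None, length: int, sim: float) -> None:
        nonlocal best
        if (length, sim) > best[0]:
            best = ((length, sim), list(chain))
        t0, r0, _ = anchors[chain[-1]]
        for j, (t, r, s) in enumerate(anchors):
            dt = t - t0
            if not (0 < dt <= max_gap):
                continue
            dr = r - r0
            for o in ((orient,) if orient is not None else (1, -1)):
                if o * dr > 0 and abs(dr) <= max_gap:
                    chain.append(j)
                    rec(chain, o, length + 1, sim + s)
                    chain.pop()

    for i, (_, _, s) in enumerate(anchors):
        rec([i], None, 1, s)
    (length, sim), idx = best
    return length, sim, idx


def extract_chains_bruteforce(
    anchors: list[tuple[int, int, float]], min_anchors: int, max_gap: int
) -> list[int]:
    """Best-first iterative extraction via exhaustive search; returns the
    anchor count of each extracted chain, in extraction order."""
    remaining = list(anchors)
    counts: list[int] = []
    while remaining:
        length, _, idx = best_chain_bruteforce(remaining, max_gap)
        if length < min_anchors:
            break
        counts.append(length)
        drop = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in drop]
    return counts


def superblock_partition_bruteforce(
    blocks: list[SyntenicBlock], min_overlap: int
) -> set[frozenset[str]]:
    """Member partition of superblocks via overlap matrix + transitive closure."""
    out: set[frozenset[str]] = set()
    chroms = sorted({b.reference_chromosome for b in blocks})
    for chrom in chroms:
        group = [b for b in blocks if b.reference_chromosome == chrom]
        n = len(group)
        mat = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                lo = max(group[i].reference_span[0], group[j].reference_span[0])
                hi = min(group[i].reference_span[1], group[j].reference_span[1])
                mat[i, j] = (hi - lo + 1) >= min_overlap
        _, labels = connected_components(csr_matrix(mat), directed=False)
        for lab in set(labels):
            members = frozenset(
                group[i].block_id for i in range(n) if labels[i] == lab
            )
            if len(members) >= 2:
                out.add(members)
    return out


def make_block(
    block_id: str, rchr: str, lo: int, hi: int, tchr: str = "t1"
) -> SyntenicBlock:
    """A minimal valid block with a prescribed reference span (test helper)."""
    if hi > lo:
        anchors = (AnchorPair(1, lo, 1.0), AnchorPair(2, hi, 1.0))
    else:
        anchors = (AnchorPair(1, lo, 1.0),)
    return SyntenicBlock(
        block_id=block_id,
        target_chromosome=tchr,
        reference_chromosome=rchr,
        anchors=anchors,
        orientation="parallel",
        target_span=(1, len(anchors)),
        reference_span=(lo, hi),
    )
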