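"""Chainer correctness: monotone gap-bounded chains, determinism, oracles."""

import numpy as np
import pytest

from oracles import extract_chains_bruteforce
from wgdsig.io import GenomeAnnotation, HomologPair
from wgdsig.synteny import (
    ChainingParams,
    extract_chains,
    filter_blocks,
    find_syntenic_blocks,
)


def _annotations(n_target=60, n_ref=120):
    t = GenomeAnnotation.from_records(
        "tgt", [(f"t{i}", "c1", 10 * i, 10 * i + 5, "+") for i in range(1, n_target + 1)]
    )
    r = GenomeAnnotation.from_records(
        "ref", [(f"r{i}", "d1", 10 * i, 10 * i + 5, "+") for i in range(1, n_ref + 1)]
    )
    return t, r


class TestFindSyntenicBlocks:
    def test_perfect_diagonal(self):
        t, r = _annotations()
        pairs = [HomologPair(f"t{i}", f"r{i}", 90.0) for i in range(1, 7)]
        blocks = find_syntenic_blocks(pairs, t, r, ChainingParams(5, 20))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "parallel"
        assert b.n_anchors == 6
        assert b.target_span == (1, 6) and b.reference_span == (1, 6)
        assert b.block_id == "c1_d1_1"

    def test_below_minl_gives_nothing(self):
        t, r = _annotations()
        pairs = [HomologPair(f"t{i}", f"r{i}", 90.0) for i in range(1, 5)]
        assert find_syntenic_blocks(pairs, t, r, ChainingParams(5, 20)) == []

    def test_parallel_and_antiparallel_blocks(self):
        # diagonal (i, i) for i=1..5 plus anti-diagonal (i, 100-i) for i=10..14
        t, r = _annotations(60, 120)
        pairs = [HomologPair(f"t{i}", f"r{i}", 80.0) for i in range(1, 6)] + [
            HomologPair(f"t{i}", f"r{100 - i}", 70.0) for i in range(10, 15)
        ]
        blocks = find_syntenic_blocks(pairs, t, r, ChainingParams(5, 20))
        assert sorted(b.orientation for b in blocks) == ["antiparallel", "parallel"]
        assert all(b.n_anchors == 5 for b in blocks)
        # cross-checked against exhaustive chain enumeration on this instance
        anchors = [(i, i, 80.0) for i in range(1, 6)] + [
            (i, 100 - i, 70.0) for i in range(10, 15)
        ]
        assert extract_chains_bruteforce(anchors, 5, 20) == [5, 5]

    def test_unresolvable_gene_is_error(self):
        t, r = _annotations()
        with pytest.raises(KeyError, match="nope"):
            find_syntenic_blocks([HomologPair("nope", "r1", 50.0)], t, r)

    def test_empty_pairs_empty_result(self):
        t, r = _annotations()
        assert find_syntenic_blocks([], t, r) == []


class TestFilterBlocks:
    def _sized_blocks(self):
        t, r = _annotations()
        pairs = (
            [HomologPair(f"t{i}", f"r{i}", 80.0) for i in range(1, 6)]
            + [HomologPair(f"t{i}", f"r{i + 30}", 80.0) for i in range(20, 24)]
            + [HomologPair(f"t{i}", f"r{i + 60}", 80.0) for i in range(40, 43)]
        )
        return find_syntenic_blocks(pairs, t, r, ChainingParams(3, 20))

    def test_rethreshold(self):
        blocks = self._sized_blocks()
        assert sorted(b.n_anchors for b in blocks) == [3, 4, 5]
        assert sorted(b.n_anchors for b in filter_blocks(blocks, 4)) == [4, 5]
        assert filter_blocks(blocks, 0) == blocks
        assert filter_blocks([], 5) == []

    def test_filtering_low_minl_equals_chaining_high_minl(self):
        t, r = _annotations()
        rng = np.random.default_rng(7)
        pairs = [
            HomologPair(
                f"t{int(rng.integers(1, 61))}",
                f"r{int(rng.integers(1, 121))}",
                float(rng.uniform(40, 100)),
            )
            for _ in range(120)
        ]
        pairs = list({(p.target_gene, p.reference_gene): p for p in pairs}.values())
        low = find_syntenic_blocks(pairs, t, r, ChainingParams(3, 10))
        high = find_syntenic_blocks(pairs, t, r, ChainingParams(5, 10))
        assert [
            (b.block_id, b.anchors) for b in filter_blocks(low, 5)
        ] == [(b.block_id, b.anchors) for b in high]


def _random_instance(rng, n, t_max=30, r_max=30):
    pts = set()
    while len(pts) < n:
        pts.add((int(rng.integers(1, t_max)), int(rng.integers(1, r_max))))
    return [(t, r, float(rng.uniform(0, 100))) for t, r in sorted(pts)]


class TestChainInvariants:
    def test_blocks_disjoint_and_valid(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            anchors = _random_instance(rng, int(rng.integers(5, 40)))
            chains = extract_chains(anchors, 3, int(rng.integers(2, 8)))
            seen = set()
            for chain, _ in chains:
                for a in chain:
                    assert a not in seen
                    seen.add(a)

    def test_block_contract_scanned(self):
        t, r = _annotations()
        rng = np.random.default_rng(5)
        pairs = [
            HomologPair(
                f"t{int(rng.integers(1, 61))}",
                f"r{int(rng.integers(1, 121))}",
                float(rng.uniform(40, 100)),
            )
            for _ in range(150)
        ]
        pairs = list({(p.target_gene, p.reference_gene): p for p in pairs}.values())
        params = ChainingParams(3, 6)
        for b in find_syntenic_blocks(pairs, t, r, params):
            b.validate(max_gap=params.max_gap)

    def test_raising_minl_never_increases_block_count(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            anchors = _random_instance(rng, 25)
            counts = [len(extract_chains(anchors, m, 5)) for m in (2, 3, 4, 5, 6)]
            assert counts == sorted(counts, reverse=True)

    def test_matches_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            anchors = _random_instance(rng, int(rng.integers(4, 11)), 12, 12)
            gap = int(rng.integers(2, 6))
            ours = [len(c) for c, _ in extract_chains(anchors, 2, gap)]
            assert ours == extract_chains_bruteforce(anchors, 2, gap)
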