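"""Simulator contracts: WGD copy counts, fractionation, rearrangements,
lethality floor, and end-to-end multiplicity behaviour."""

import math

import numpy as np
import pytest

from wgdsig.simulate import (
    EvolutionScenario,
    FractionationParams,
    WGDEvent,
    apply_fractionation,
    apply_rearrangements,
    apply_wgd,
    simulate_ancestor,
    simulate_pair,
)
from wgdsig.superblocks import OverlapParams, build_superblocks, multiplicity_distribution
from wgdsig.synteny import ChainingParams, find_syntenic_blocks


class TestAncestor:
    def test_equal_split(self):
        state = simulate_ancestor(100, 4)
        assert [len(c) for c in state.chromosomes] == [25, 25, 25, 25]
        assert state.n_copies() == 100

    def test_one_gene_per_chromosome(self):
        state = simulate_ancestor(5, 5)
        assert [len(c) for c in state.chromosomes] == [1] * 5

    def test_fewer_genes_than_chromosomes_is_error(self):
        with pytest.raises(ValueError):
            simulate_ancestor(3, 4)


class TestWGD:
    def test_duplication_doubles_everything(self):
        state = apply_wgd(simulate_ancestor(100, 4), 2)
        assert state.n_copies() == 200
        assert len(state.chromosomes) == 8
        assert all(k == 2 for k in state.copy_counts().values())

    def test_triplication(self):
        state = apply_wgd(simulate_ancestor(100, 4), 3)
        assert state.n_copies() == 300

    def test_two_rounds_compose(self):
        state = apply_wgd(apply_wgd(simulate_ancestor(100, 4), 2), 2)
        assert state.n_copies() == 400
        assert all(k == 4 for k in state.copy_counts().values())
        # copy paths identify the subgenome at each event
        paths = {path for chrom in state.chromosomes for _, path, _ in chrom}
        assert paths == {(0, 0), (0, 1), (1, 0), (1, 1)}


class TestFractionation:
    def test_zero_duration_is_identity(self):
        state = apply_wgd(simulate_ancestor(50, 2), 2)
        before = [list(c) for c in state.chromosomes]
        apply_fractionation(state, 1.0, 0.0, 1)
        assert state.chromosomes == before

    def test_infinite_loss_keeps_exactly_one_copy(self):
        state = apply_wgd(apply_wgd(simulate_ancestor(200, 4), 2), 2)
        apply_fractionation(state, 1.0, 1e9, 1)
        assert state.n_copies() == 200
        assert all(k == 1 for k in state.copy_counts().values())

    def test_survival_matches_exponential(self):
        # lambda*t = 1 on 1000 duplicate pairs: extra copies ~ Bin(1000, e^-1)
        extras = []
        for seed in range(30):
            state = apply_wgd(simulate_ancestor(1000, 4), 2)
            apply_fractionation(state, 2.0, 0.5, seed)
            extras.append(state.n_copies() - 1000)
        mean = np.mean(extras)
        se = math.sqrt(1000 * math.exp(-1) * (1 - math.exp(-1)) / len(extras))
        assert abs(mean - 1000 * math.exp(-1)) < 4 * se

    def test_deterministic_given_seed(self):
        s1 = apply_wgd(simulate_ancestor(300, 3), 2)
        s2 = apply_wgd(simulate_ancestor(300, 3), 2)
        apply_fractionation(s1, 0.9, 1.0, 42)
        apply_fractionation(s2, 0.9, 1.0, 42)
        assert s1.chromosomes == s2.chromosomes


class TestRearrangements:
    def test_zero_counts_identity(self):
        state = simulate_ancestor(60, 3)
        before = [list(c) for c in state.chromosomes]
        apply_rearrangements(state, 0, 0, 7)
        assert state.chromosomes == before

    def test_single_inversion_reverses_one_interval(self):
        state = simulate_ancestor(60, 1)
        original = list(state.chromosomes[0])
        apply_rearrangements(state, 1, 0, 99)
        result = state.chromosomes[0]
        diffs = [i for i, (a, b) in enumerate(zip(original, result)) if a != b]
        assert diffs  # seed 99 hits a non-trivial interval
        i, j = diffs[0], diffs[-1]
        segment = result[i : j + 1]
        expected = [(anc, path, -strand) for anc, path, strand in
                    reversed(original[i : j + 1])]
        assert segment == expected

    def test_gene_content_conserved(self):
        rng_seeds = range(5)
        for seed in rng_seeds:
            state = apply_wgd(simulate_ancestor(100, 4), 2)
            before = sorted(
                (anc, path) for c in state.chromosomes for anc, path, _ in c
            )
            apply_rearrangements(state, 10, 5, seed)
            after = sorted(
                (anc, path) for c in state.chromosomes for anc, path, _ in c
            )
            assert before == after


class TestScenarioValidation:
    def test_event_times_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            EvolutionScenario(target_events=[WGDEvent(0.3), WGDEvent(0.5)])

    def test_target_events_post_date_speciation(self):
        with pytest.raises(ValueError):
            EvolutionScenario(speciation_time=1.0, target_events=[WGDEvent(1.5)])

    def test_shared_events_pre_date_speciation(self):
        with pytest.raises(ValueError):
            EvolutionScenario(speciation_time=1.0, shared_events=[WGDEvent(0.5)])


class TestSimulatePair:
    @staticmethod
    def _superblock_mass(pair):
        """Number of blocks participating in any superblock."""
        blocks = find_syntenic_blocks(
            pair.pairs, pair.target, pair.reference, ChainingParams(5, 20)
        )
        dist = multiplicity_distribution(
            build_superblocks(blocks, OverlapParams(5))
        )
        return sum(b * n for b, n in dist.counts.items()), len(blocks), dist

    def test_no_wgd_control(self):
        sc = EvolutionScenario(
            n_ancestral_genes=400, n_chromosomes=4, n_inversions=5,
            n_translocations=2, seed=11,
        )
        pair = simulate_pair(sc)
        # single-copy everywhere: homologs are 1-to-1 per ancestral gene
        assert len(pair.target) == 400 and len(pair.reference) == 400
        assert len(pair.pairs) == 400
        assert all(k == 1 for k in pair.target_copy_counts.values())
        # without WGD only rearrangement interleaving creates span overlap,
        # so far fewer blocks join superblocks than in a matched WGD scenario
        mass0, n0, _ = self._superblock_mass(pair)
        wgd_pair = simulate_pair(
            EvolutionScenario(
                n_ancestral_genes=400, n_chromosomes=4, n_inversions=5,
                n_translocations=2, target_events=[WGDEvent(0.5)], seed=11,
            )
        )
        mass1, n1, _ = self._superblock_mass(wgd_pair)
        assert mass0 / n0 < 0.5 * (mass1 / n1)

    def test_one_wgd_concentrates_multiplicity_at_two(self):
        # rearrangement-free so the WGD effect is seen in isolation
        sc = EvolutionScenario(
            n_ancestral_genes=800, n_chromosomes=4,
            target_events=[WGDEvent(0.5)],
            fractionation=FractionationParams(0.3),
            n_inversions=0, n_translocations=0, seed=5,
        )
        pair = simulate_pair(sc)
        # most ancestral genes keep both post-WGD copies
        two_copy = sum(1 for k in pair.target_copy_counts.values() if k == 2)
        assert two_copy > 0.6 * sc.n_ancestral_genes
        _, _, dist = self._superblock_mass(pair)
        assert dist.counts, "one WGD must produce superblocks"
        assert max(dist.counts) == 2
        assert dist.counts[2] >= 0.9 * dist.total_superblocks()

    def test_lethality_floor_and_copy_bound(self):
        sc = EvolutionScenario(
            n_ancestral_genes=300, n_chromosomes=3,
            shared_events=[WGDEvent(1.5)],
            target_events=[WGDEvent(0.6), WGDEvent(0.3)],
            fractionation=FractionationParams(1.2), seed=2,
        )
        pair = simulate_pair(sc)
        counts = pair.target_copy_counts
        assert set(counts) == set(range(300))  # every gene survives somewhere
        assert min(counts.values()) >= 1
        assert max(counts.values()) <= 2 * 2 * 2  # product of ploidy factors

    def test_determinism(self):
        sc = EvolutionScenario(n_ancestral_genes=200, n_chromosomes=2,
                               target_events=[WGDEvent(0.5)], seed=8)
        p1, p2 = simulate_pair(sc), simulate_pair(sc)
        assert [(x.target_gene, x.reference_gene, x.similarity)
                for x in p1.pairs] == [
            (x.target_gene, x.reference_gene, x.similarity) for x in p2.pairs
        ]

    def test_similarity_tracks_divergence(self):
        sc = EvolutionScenario(
            n_ancestral_genes=400, n_chromosomes=4, speciation_time=1.0,
            shared_events=[WGDEvent(1.5)], similarity_noise_sd=0.5, seed=6,
        )
        pair = simulate_pair(sc)
        sims = [p.similarity for p in pair.pairs]
        # two modes: orthologs near 100*exp(-0.21) ~ 81, homoeologs near 73
        ortho = [s for s in sims if s > 77]
        homoeo = [s for s in sims if s <= 77]
        assert ortho and homoeo
        assert abs(np.median(ortho) - 81) < 2
        assert abs(np.median(homoeo) - 73) < 2
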