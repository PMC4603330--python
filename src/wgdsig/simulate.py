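"""Genome-evolution simulator with known whole-genome-duplication truth.

Generates target/reference annotation pairs plus homolog tables from a
scripted history: an ancestral gene order undergoes optional shared
polyploidies on the root lineage, splits at a speciation time, and each
descendant lineage then experiences its own WGD/triplication events,
exponential fractionation of redundant gene copies (rate ``lambda`` per
copy per time unit), and chromosomal rearrangements.  Homolog pairs
between the two genomes carry percent similarities that decay
exponentially with divergence time plus truncated Gaussian noise.

Two modelling commitments matter downstream:

* **Fractionation with a lethality floor.**  Over an interval of length
  ``d``, each copy of an ancestral gene beyond the first is lost with
  probability ``1 - exp(-lambda * d)``; the lost copies are drawn
  uniformly from the gene's current copies, and the last copy of a gene
  is never deleted (loss of all copies is assumed lethal).  For a
  duplicate pair this leaves the extra copy surviving with probability
  ``exp(-lambda * t)``, and the process composes memorylessly across
  intervals.
* **Reference lineage is WGD-free by default**, so superblock
  multiplicity in the target maps cleanly to target history; scenarios
  may script reference (or shared pre-split) events for stress tests.

All randomness flows from the scenario seed through one
``numpy.random.Generator``, so simulations are exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import GenomeAnnotation, HomologPair

__all__ = [
    "WGDEvent",
    "FractionationParams",
    "EvolutionScenario",
    "SimulatedPair",
    "GenomeState",
    "simulate_ancestor",
    "apply_wgd",
    "apply_fractionation",
    "apply_rearrangements",
    "simulate_pair",
    "simulate_panel",
]


@dataclass(frozen=True)
class WGDEvent:
    """A polyploidy event: time before present and ploidy factor.

    ``ploidy_factor`` 2 is a whole-genome duplication, 3 a triplication
    (like the core-eudicot gamma event).
    """

    time: float
    ploidy_factor: int = 2

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.ploidy_factor < 2:
            raise ValueError("ploidy_factor must be >= 2")


@dataclass(frozen=True)
class FractionationParams:
    """Per-copy exponential loss rate lambda (per time unit)."""

    lambda_rate: float = 0.8

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be > 0")


@dataclass
class EvolutionScenario:
    """Scripted two-lineage history driving :func:`simulate_pair`.

    Times are in arbitrary units before present; ``target_events`` (and
    optional ``reference_events``) must post-date the speciation,
    ``shared_events`` must pre-date it, and each list must be strictly
    decreasing in time (oldest first).  ``similarity_rate`` sets the
    exponential decay of percent similarity with divergence time; the
    default 0.21 puts orthologs from a divergence one time unit ago near
    81% similarity and homoeologs from a shared event at 1.5 units near
    73%.
    """

    n_ancestral_genes: int = 2000
    n_chromosomes: int = 8
    speciation_time: float = 1.0
    target_events: list[WGDEvent] = field(default_factory=list)
    fractionation: FractionationParams = field(default_factory=FractionationParams)
    n_inversions: int = 20
    n_translocations: int = 5
    similarity_rate: float = 0.21
    similarity_noise_sd: float = 1.5
    shared_events: list[WGDEvent] = field(default_factory=list)
    reference_events: list[WGDEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError("need n_ancestral_genes >= n_chromosomes >= 1")
        if self.speciation_time <= 0:
            raise ValueError("speciation_time must be > 0")
        for name, events, older in (
            ("shared_events", self.shared_events, True),
            ("target_events", self.target_events, False),
            ("reference_events", self.reference_events, False),
        ):
            times = [e.time for e in events]
            if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"{name} times must be strictly decreasing")
            for t in times:
                if older and t <= self.speciation_time:
                    raise ValueError("shared events must pre-date speciation")
                if not older and t >= self.speciation_time:
                    raise ValueError(f"{name} must post-date speciation")


# A gene copy is (ancestral_gene_index, copy_path, strand) where copy_path
# is a tuple with one entry per WGD event the copy has lived through.
Copy = tuple[int, tuple[int, ...], int]


@dataclass
class GenomeState:
    """Mutable in-flight genome: ordered gene copies per chromosome."""

    chromosomes: list[list[Copy]]
    event_times: list[float] = field(default_factory=list)

    def clone(self) -> "GenomeState":
        return GenomeState(
            chromosomes=[list(c) for c in self.chromosomes],
            event_times=list(self.event_times),
        )

    def n_copies(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def copy_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for chrom in self.chromosomes:
            for anc, _, _ in chrom:
                counts[anc] = counts.get(anc, 0) + 1
        return counts


def simulate_ancestor(
    n_genes: int, n_chromosomes: int, seed: int = 0
) -> GenomeState:
    """Ancestral single-copy genome: genes 0..n-1 in near-equal contiguous runs."""
    if not (n_genes >= n_chromosomes >= 1):
        raise ValueError("need n_genes >= n_chromosomes >= 1")
    base, extra = divmod(n_genes, n_chromosomes)
    chroms: list[list[Copy]] = []
    g = 0
    for i in range(n_chromosomes):
        size = base + (1 if i < extra else 0)
        chroms.append([(g + j, (), 1) for j in range(size)])
        g += size
    return GenomeState(chromosomes=chroms)


def apply_wgd(
    state: GenomeState, ploidy_factor: int, time: float | None = None
) -> GenomeState:
    """Polyploidise in place: every chromosome gains ploidy_factor-1 copies.

    Each copy's path records which post-event subgenome it belongs to, so
    divergence times between copies remain computable.
    """
    if ploidy_factor < 2:
        raise ValueError("ploidy_factor must be >= 2")
    originals = state.chromosomes
    new_chroms: list[list[Copy]] = [
        [(anc, path + (0,), strand) for anc, path, strand in chrom]
        for chrom in originals
    ]
    for f in range(1, ploidy_factor):
        for chrom in originals:
            new_chroms.append(
                [(anc, path + (f,), strand) for anc, path, strand in chrom]
            )
    state.chromosomes = new_chroms
    state.event_times.append(time if time is not None else math.nan)
    return state


def apply_fractionation(
    state: GenomeState,
    lambda_rate: float,
    duration: float,
    rng: np.random.Generator | int,
) -> GenomeState:
    """Lose redundant copies over an interval; never the last copy of a gene.

    For each ancestral gene with k > 1 copies, the number of losses is
    Binomial(k - 1, 1 - exp(-lambda * duration)) and the lost copies are
    chosen uniformly, implementing exponential duplicate loss with a
    lethality floor.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return state
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    p_loss = 1.0 - math.exp(-lambda_rate * duration)
    positions: dict[int, list[tuple[int, int]]] = {}
    for ci, chrom in enumerate(state.chromosomes):
        for pi, (anc, _, _) in enumerate(chrom):
            positions.setdefault(anc, []).append((ci, pi))
    doomed: set[tuple[int, int]] = set()
    for anc in sorted(positions):
        locs = positions[anc]
        k = len(locs)
        if k < 2:
            continue
        n_loss = int(rng.binomial(k - 1, p_loss))
        if n_loss == 0:
            continue
        for idx in rng.choice(k, size=n_loss, replace=False):
            doomed.add(locs[int(idx)])
    state.chromosomes = [
        [copy for pi, copy in enumerate(chrom) if (ci, pi) not in doomed]
        for ci, chrom in enumerate(state.chromosomes)
    ]
    return state


def apply_rearrangements(
    state: GenomeState,
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator | int,
) -> GenomeState:
    """Apply segmental inversions and inter-chromosomal translocations.

    Inversions reverse a uniformly chosen interval of a uniformly chosen
    chromosome (flipping strands); translocations excise a uniform
    interval and insert it at a uniform position on another chromosome.
    Gene content is conserved exactly.
    """
    if n_inversions < 0 or n_translocations < 0:
        raise ValueError("rearrangement counts must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    chroms = state.chromosomes
    for _ in range(n_inversions):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            break
        ci = eligible[int(rng.integers(len(eligible)))]
        n = len(chroms[ci])
        i, j = sorted(int(x) for x in rng.integers(0, n, size=2))
        segment = chroms[ci][i : j + 1]
        chroms[ci][i : j + 1] = [
            (anc, path, -strand) for anc, path, strand in reversed(segment)
        ]
    for _ in range(n_translocations):
        sources = [i for i, c in enumerate(chroms) if len(c) >= 1]
        if len(chroms) < 2 or not sources:
            break
        src = sources[int(rng.integers(len(sources)))]
        n = len(chroms[src])
        i, j = sorted(int(x) for x in rng.integers(0, n, size=2))
        segment = chroms[src][i : j + 1]
        del chroms[src][i : j + 1]
        others = [k for k in range(len(chroms)) if k != src]
        dst = others[int(rng.integers(len(others)))]
        pos = int(rng.integers(0, len(chroms[dst]) + 1))
        chroms[dst][pos:pos] = segment
    return state


@dataclass
class SimulatedPair:
    """A simulated target/reference comparison with its generating truth."""

    target: GenomeAnnotation
    reference: GenomeAnnotation
    pairs: list[HomologPair]
    truth: EvolutionScenario
    target_copy_counts: dict[int, int] = field(default_factory=dict)
    reference_copy_counts: dict[int, int] = field(default_factory=dict)


def _copy_gene_id(prefix: str, anc: int, path: tuple[int, ...]) -> str:
    suffix = "".join(str(p) for p in path)
    return f"{prefix}_g{anc}_{suffix or 'x'}"


def _state_to_annotation(
    state: GenomeState, genome_id: str, prefix: str
) -> tuple[GenomeAnnotation, dict[str, Copy]]:
    records = []
    id_to_copy: dict[str, Copy] = {}
    for ci, chrom in enumerate(state.chromosomes, 1):
        cname = f"{prefix}{ci}"
        for pos, (anc, path, strand) in enumerate(chrom, 1):
            gid = _copy_gene_id(prefix, anc, path)
            start = (pos - 1) * 1000 + 1
            records.append((gid, cname, start, start + 899, "+" if strand > 0 else "-"))
            id_to_copy[gid] = (anc, path, strand)
    return GenomeAnnotation.from_records(genome_id, records), id_to_copy


def _evolve_lineage(
    state: GenomeState,
    events: Sequence[WGDEvent],
    start_time: float,
    lam: float,
    n_inversions: int,
    n_translocations: int,
    rng: np.random.Generator,
) -> GenomeState:
    now = start_time
    for ev in events:
        apply_fractionation(state, lam, now - ev.time, rng)
        apply_wgd(state, ev.ploidy_factor, ev.time)
        now = ev.time
    apply_fractionation(state, lam, now, rng)
    apply_rearrangements(state, n_inversions, n_translocations, rng)
    return state


def _divergence_time(
    path_a: tuple[int, ...],
    path_b: tuple[int, ...],
    shared_times: Sequence[float],
    speciation_time: float,
) -> float:
    for i, t in enumerate(shared_times):
        if path_a[i] != path_b[i]:
            return t
    return speciation_time


def _similarity(
    div_time: float, rate: float, noise_sd: float, rng: np.random.Generator
) -> float:
    base = 100.0 * math.exp(-rate * div_time)
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    noise = max(-3 * noise_sd, min(3 * noise_sd, noise))
    return max(0.0, min(100.0, base + noise))


def _check_lethality_floor(state: GenomeState, n_genes: int, label: str) -> None:
    counts = state.copy_counts()
    missing = [g for g in range(n_genes) if counts.get(g, 0) < 1]
    if missing:
        raise AssertionError(
            f"{label}: lethality floor violated for genes {missing[:5]}..."
        )


def _shared_history(
    scenario: EvolutionScenario, rng: np.random.Generator
) -> tuple[GenomeState, list[float]]:
    state = simulate_ancestor(scenario.n_ancestral_genes, scenario.n_chromosomes)
    lam = scenario.fractionation.lambda_rate
    prev: float | None = None
    for ev in scenario.shared_events:
        if prev is not None:
            apply_fractionation(state, lam, prev - ev.time, rng)
        apply_wgd(state, ev.ploidy_factor, ev.time)
        prev = ev.time
    if prev is not None:
        apply_fractionation(state, lam, prev - scenario.speciation_time, rng)
    return state, [e.time for e in scenario.shared_events]


def simulate_pair(scenario: EvolutionScenario) -> SimulatedPair:
    """Run a full two-lineage scenario and emit annotations + homolog pairs.

    The root lineage carries any shared events, splits at the speciation
    time, and each descendant evolves independently.  A homolog pair is
    emitted for every (target copy, reference copy) sharing an ancestral
    gene, with similarity decaying from the pair's divergence time — the
    speciation for orthologous copies, the shared event at which their
    subgenome paths parted for homoeologous ones.
    """
    rng = np.random.default_rng(scenario.seed)
    root, shared_times = _shared_history(scenario, rng)
    lam = scenario.fractionation.lambda_rate
    ref_state = _evolve_lineage(
        root.clone(), scenario.reference_events, scenario.speciation_time,
        lam, scenario.n_inversions, scenario.n_translocations, rng,
    )
    tgt_state = _evolve_lineage(
        root.clone(), scenario.target_events, scenario.speciation_time,
        lam, scenario.n_inversions, scenario.n_translocations, rng,
    )
    for label, st in (("reference", ref_state), ("target", tgt_state)):
        _check_lethality_floor(st, scenario.n_ancestral_genes, label)
    target_ann, tgt_copies = _state_to_annotation(tgt_state, "target", "T")
    ref_ann, ref_copies = _state_to_annotation(ref_state, "reference", "R")
    n_shared = len(shared_times)
    by_anc_ref: dict[int, list[tuple[str, tuple[int, ...]]]] = {}
    for gid, (anc, path, _) in ref_copies.items():
        by_anc_ref.setdefault(anc, []).append((gid, path[:n_shared]))
    pairs: list[HomologPair] = []
    for gid_t, (anc, path_t, _) in tgt_copies.items():
        for gid_r, path_r in by_anc_ref.get(anc, []):
            div = _divergence_time(
                path_t[:n_shared], path_r, shared_times, scenario.speciation_time
            )
            sim = _similarity(
                div, scenario.similarity_rate, scenario.similarity_noise_sd, rng
            )
            pairs.append(HomologPair(gid_t, gid_r, sim))
    return SimulatedPair(
        target=target_ann,
        reference=ref_ann,
        pairs=pairs,
        truth=scenario,
        target_copy_counts=tgt_state.copy_counts(),
        reference_copy_counts=ref_state.copy_counts(),
    )


def simulate_panel(
    genome_events: dict[str, Sequence[WGDEvent]],
    base: EvolutionScenario,
) -> tuple[dict[str, GenomeAnnotation], dict[tuple[str, str], list[HomologPair]]]:
    """Simulate several genomes radiating from one common ancestor.

    Every genome in ``genome_events`` descends from the same root (with
    ``base.shared_events`` applied before the radiation at
    ``base.speciation_time``) and then evolves with its own WGD list and
    the shared fractionation/rearrangement settings.  Returns annotations
    keyed by genome id and homolog tables keyed by ordered (target,
    reference) id pairs — the two orientations of a pair contain the same
    homologies with the gene columns swapped.
    """
    rng = np.random.default_rng(base.seed)
    root, shared_times = _shared_history(base, rng)
    lam = base.fractionation.lambda_rate
    n_shared = len(shared_times)
    states: dict[str, GenomeState] = {}
    for gid, events in genome_events.items():
        for ev in events:
            if ev.time >= base.speciation_time:
                raise ValueError("lineage events must post-date the radiation")
        states[gid] = _evolve_lineage(
            root.clone(), list(events), base.speciation_time,
            lam, base.n_inversions, base.n_translocations, rng,
        )
        _check_lethality_floor(states[gid], base.n_ancestral_genes, gid)
    annotations: dict[str, GenomeAnnotation] = {}
    copies: dict[str, dict[str, Copy]] = {}
    for i, gid in enumerate(genome_events):
        ann, cp = _state_to_annotation(states[gid], gid, f"G{i}c")
        annotations[gid] = ann
        copies[gid] = cp
    tables: dict[tuple[str, str], list[HomologPair]] = {}
    ids = list(genome_events)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            by_anc_b: dict[int, list[tuple[str, tuple[int, ...]]]] = {}
            for gid, (anc, path, _) in copies[gb].items():
                by_anc_b.setdefault(anc, []).append((gid, path[:n_shared]))
            ab: list[HomologPair] = []
            ba: list[HomologPair] = []
            for gid_a, (anc, path_a, _) in copies[ga].items():
                for gid_b, path_b in by_anc_b.get(anc, []):
                    div = _divergence_time(
                        path_a[:n_shared], path_b, shared_times,
                        base.speciation_time,
                    )
                    sim = _similarity(
                        div, base.similarity_rate, base.similarity_noise_sd, rng
                    )
                    ab.append(HomologPair(gid_a, gid_b, sim))
                    ba.append(HomologPair(gid_b, gid_a, sim))
            tables[(ga, gb)] = ab
            tables[(gb, ga)] = ba
    return annotations, tables


def write_truth(pair: SimulatedPair, path: str | Path) -> None:
    """Dump the scenario and per-gene copy counts as JSON."""
    payload = {
        "scenario": asdict(pair.truth),
        "target_copy_counts": {str(k): v for k, v in pair.target_copy_counts.items()},
        "reference_copy_counts": {
            str(k): v for k, v in pair.reference_copy_counts.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
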