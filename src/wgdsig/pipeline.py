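"""Orchestration of the full panel analysis: blocks → superblocks → fits → ranking.

The panel design crosses every ordered (target, reference) pair with
sweeps of minL (block validation), T (reference overlap in genes) and
B_min (tail cutoff).  ``analyze_pair`` runs one ordered pair across the
sweeps; ``run_panel`` reads a config, runs every pair, and writes the
cell table, win matrix, ranking and a machine-readable manifest.  Reruns
with identical inputs and seed are byte-identical.

Chaining is performed once per ordered pair at the smallest minL in the
sweep and re-thresholded for the larger values: best-first extraction
yields blocks in non-increasing anchor-count order, so filtering is
exactly equivalent to re-chaining (and much cheaper).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .io import (
    GenomeAnnotation,
    HomologPair,
    read_gene_annotations,
    read_homolog_pairs,
)
from .ranking import (
    ComparisonCell,
    GenomeRanking,
    WinMatrix,
    pairwise_wins,
    rank_genomes,
)
from .superblocks import MultiplicityDistribution, OverlapParams, build_superblocks, multiplicity_distribution
from .synteny import ChainingParams, filter_blocks, find_syntenic_blocks
from .tailfit import fit_all_cutoffs

__all__ = ["RunConfig", "analyze_pair", "run_panel", "PanelResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Panel run configuration (see ``RunConfig.from_yaml`` for the file form).

    ``homologs`` maps ordered (target, reference) id pairs to TSV paths; a
    missing orientation falls back to the swapped pair's table with the
    gene columns exchanged.
    """

    genomes: dict[str, str]
    homologs: dict[tuple[str, str], str]
    output_dir: str
    minl: tuple[int, ...] = (3, 4, 5)
    overlap: tuple[int, ...] = (5, 10)
    cutoffs: tuple[int, ...] = (2, 3, 4)
    max_gap: int = 20
    seed: int = 0
    annotation_format: str = "gff3"

    def __post_init__(self) -> None:
        for sweep, name in ((self.minl, "minl"), (self.overlap, "overlap"),
                            (self.cutoffs, "cutoffs")):
            if not sweep:
                raise ValueError(f"{name} sweep must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        homologs = {
            tuple(k.split(",")): v for k, v in raw.get("homologs", {}).items()
        }
        for key in homologs:
            if len(key) != 2:
                raise ValueError(f"homolog key {key} must be 'target,reference'")
        return cls(
            genomes=dict(raw["genomes"]),
            homologs=homologs,  # type: ignore[arg-type]
            output_dir=raw["output_dir"],
            minl=tuple(raw.get("minl", (3, 4, 5))),
            overlap=tuple(raw.get("overlap", (5, 10))),
            cutoffs=tuple(raw.get("cutoffs", (2, 3, 4))),
            max_gap=int(raw.get("max_gap", 20)),
            seed=int(raw.get("seed", 0)),
            annotation_format=raw.get("annotation_format", "gff3"),
        )


def analyze_pair(
    target: GenomeAnnotation,
    reference: GenomeAnnotation,
    pairs: Sequence[HomologPair],
    minl_values: Sequence[int] = (3, 4, 5),
    overlap_values: Sequence[int] = (5,),
    cutoff_values: Sequence[int] = (2, 3, 4),
    max_gap: int = 20,
) -> list[ComparisonCell]:
    """All comparison cells for one ordered (target, reference) pair.

    Returns one :class:`ComparisonCell` per (minL, T, B_min) combination;
    cells whose tail fit is undefined carry ``c=None``.
    """
    base_blocks = find_syntenic_blocks(
        pairs, target, reference, ChainingParams(min(minl_values), max_gap)
    )
    cells: list[ComparisonCell] = []
    for minl in minl_values:
        blocks = filter_blocks(base_blocks, minl)
        for T in overlap_values:
            sbs = build_superblocks(blocks, OverlapParams(T))
            dist = multiplicity_distribution(
                sbs, (target.genome_id, reference.genome_id, minl, T)
            )
            fits = fit_all_cutoffs(dist, tuple(cutoff_values))
            for b_min, fit in fits.items():
                cells.append(
                    ComparisonCell(
                        target_id=target.genome_id,
                        reference_id=reference.genome_id,
                        min_anchors=minl,
                        tail_cutoff=b_min,
                        overlap_T=T,
                        c=None if fit is None else fit.c,
                    )
                )
                log.info(
                    "cell %s vs %s minL=%d T=%d B_min=%d -> c=%s",
                    target.genome_id, reference.genome_id, minl, T, b_min,
                    "NA" if fit is None else f"{fit.c:.4f}",
                )
    return cells


@dataclass
class PanelResult:
    cells: list[ComparisonCell]
    matrix: WinMatrix
    ranking: GenomeRanking
    distributions: list[MultiplicityDistribution] = field(default_factory=list)


def run_panel_in_memory(
    annotations: Mapping[str, GenomeAnnotation],
    homologs: Mapping[tuple[str, str], Sequence[HomologPair]],
    minl_values: Sequence[int] = (3, 4, 5),
    overlap_values: Sequence[int] = (5,),
    cutoff_values: Sequence[int] = (2, 3, 4),
    max_gap: int = 20,
) -> PanelResult:
    """Run every ordered pair of a panel already loaded in memory."""
    ids = list(annotations)
    cells: list[ComparisonCell] = []
    for t in ids:
        for r in ids:
            if t == r:
                continue
            pairs = homologs.get((t, r))
            if pairs is None:
                swapped = homologs.get((r, t))
                if swapped is None:
                    raise ValueError(f"no homolog table for pair ({t}, {r})")
                pairs = [
                    HomologPair(p.reference_gene, p.target_gene, p.similarity)
                    for p in swapped
                ]
            cells.extend(
                analyze_pair(
                    annotations[t], annotations[r], pairs,
                    minl_values, overlap_values, cutoff_values, max_gap,
                )
            )
    matrix = pairwise_wins(cells)
    return PanelResult(cells=cells, matrix=matrix, ranking=rank_genomes(matrix))


def _write_cells_tsv(cells: Sequence[ComparisonCell], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\treference\tminL\toverlap_T\tB_min\tc\n")
        for cell in cells:
            c = "NA" if cell.c is None else f"{cell.c:.10g}"
            fh.write(
                f"{cell.target_id}\t{cell.reference_id}\t{cell.min_anchors}\t"
                f"{cell.overlap_T}\t{cell.tail_cutoff}\t{c}\n"
            )


def _write_win_matrix_tsv(matrix: WinMatrix, path: Path) -> None:
    ids = matrix.genomes
    with open(path, "w") as fh:
        fh.write("wins\t" + "\t".join(ids) + "\n")
        for g in ids:
            row = [str(matrix.wins.get((g, h), 0)) if g != h else "." for h in ids]
            fh.write(g + "\t" + "\t".join(row) + "\n")
        fh.write("comparable\t" + "\t".join(ids) + "\n")
        for g in ids:
            row = [
                str(matrix.comparable.get((g, h), 0)) if g != h else "." for h in ids
            ]
            fh.write(g + "\t" + "\t".join(row) + "\n")


def _write_ranking_tsv(ranking: GenomeRanking, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgenome\tdominance\ttotal_wins\n")
        for e in ranking.entries:
            fh.write(f"{e.rank}\t{e.genome_id}\t{e.dominance}\t{e.total_wins}\n")


def run_panel(config: RunConfig) -> PanelResult:
    """Execute the full panel from files and write all outputs.

    Validates that every referenced input exists before any cell runs;
    per-cell fit failures are recorded as missing, never fatal.  Writes
    ``cells.tsv``, ``wins.tsv``, ``ranking.tsv`` and ``manifest.json``
    into the output directory.
    """
    missing = [p for p in config.genomes.values() if not Path(p).exists()]
    for key, p in config.homologs.items():
        if not Path(p).exists():
            missing.append(p)
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    ids = list(config.genomes)
    for t in ids:
        for r in ids:
            if t != r and (t, r) not in config.homologs and (r, t) not in config.homologs:
                raise FileNotFoundError(f"no homolog table for pair ({t}, {r})")
    annotations = {
        gid: read_gene_annotations(path, config.annotation_format, genome_id=gid)
        for gid, path in config.genomes.items()
    }
    homologs = {
        key: read_homolog_pairs(path) for key, path in config.homologs.items()
    }
    result = run_panel_in_memory(
        annotations, homologs, config.minl, config.overlap, config.cutoffs,
        config.max_gap,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_cells_tsv(result.cells, out / "cells.tsv")
    _write_win_matrix_tsv(result.matrix, out / "wins.tsv")
    _write_ranking_tsv(result.ranking, out / "ranking.tsv")
    manifest = {
        "wgdsig_version": __version__,
        "genomes": config.genomes,
        "homologs": {f"{t},{r}": p for (t, r), p in config.homologs.items()},
        "minl": list(config.minl),
        "overlap": list(config.overlap),
        "cutoffs": list(config.cutoffs),
        "max_gap": config.max_gap,
        "seed": config.seed,
        "n_cells": len(result.cells),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return result
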