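"""Readers and writers for the plain-text formats the pipeline consumes.

Three kinds of input feed the analysis:

* gene annotations (GFF3 ``gene`` records or 6-column BED), from which
  per-chromosome *gene ordinals* are derived — every downstream distance
  and overlap is measured in genes, not base pairs;
* homolog-pair tables (TSV: target gene, reference gene, percent
  similarity), typically BLAST-derived;
* precomputed syntenic blocks in a DAGchainer-style text dialect, so that
  blocks produced by external synteny tools can be imported directly.

Writers emit the same dialects the readers accept, bit-compatibly, so a
write/read round trip reproduces ordinals and anchor sets exactly.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from gffutils.feature import feature_from_line

__all__ = [
    "GeneAnnotation",
    "GenomeAnnotation",
    "HomologPair",
    "AnnotationError",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_homolog_pairs",
    "write_homolog_pairs",
    "read_dagchainer_blocks",
    "write_dagchainer_blocks",
    "similarity_distribution",
]


class AnnotationError(ValueError):
    """Raised when an annotation or homolog file violates its contract."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: bp coordinates for provenance, plus its gene ordinal.

    ``ordinal`` is the 1-based rank of the gene along its chromosome by
    ascending start position (ties broken by end, then gene_id).  All
    synteny and overlap computation uses ordinals.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """All genes of one genome with per-chromosome ordinal coordinates."""

    genome_id: str
    genes: dict[str, GeneAnnotation] = field(default_factory=dict)
    chromosomes: list[str] = field(default_factory=list)

    @classmethod
    def from_records(
        cls,
        genome_id: str,
        records: Iterable[tuple[str, str, int, int, str]],
    ) -> "GenomeAnnotation":
        """Build from (gene_id, chromosome, start, end, strand) tuples.

        Ordinals are assigned per chromosome by (start, end, gene_id);
        chromosomes are listed in first-appearance order.
        """
        recs = list(records)
        if not recs:
            raise AnnotationError(f"{genome_id}: no gene records")
        seen: set[str] = set()
        chroms: list[str] = []
        by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
        for rec in recs:
            gid, chrom = rec[0], rec[1]
            if gid in seen:
                raise AnnotationError(f"{genome_id}: duplicate gene_id {gid!r}")
            seen.add(gid)
            if chrom not in by_chrom:
                by_chrom[chrom] = []
                chroms.append(chrom)
            by_chrom[chrom].append(rec)
        genes: dict[str, GeneAnnotation] = {}
        for chrom in chroms:
            ordered = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
            for ordinal, (gid, _, start, end, strand) in enumerate(ordered, 1):
                genes[gid] = GeneAnnotation(gid, chrom, start, end, strand, ordinal)
        return cls(genome_id=genome_id, genes=genes, chromosomes=chroms)

    def gene(self, gene_id: str) -> GeneAnnotation:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None

    def chromosome_genes(self, chromosome: str) -> list[GeneAnnotation]:
        """Genes of one chromosome in ordinal order."""
        return sorted(
            (g for g in self.genes.values() if g.chromosome == chromosome),
            key=lambda g: g.ordinal,
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HomologPair:
    """A homologous gene pair between target and reference genomes."""

    target_gene: str
    reference_gene: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 100.0:
            raise AnnotationError(
                f"similarity {self.similarity} outside [0, 100] "
                f"for pair ({self.target_gene}, {self.reference_gene})"
            )


# ---------------------------------------------------------------------------
# gene annotations


def read_gene_annotations(
    path: str | Path, format: str, genome_id: str | None = None
) -> GenomeAnnotation:
    """Read a GFF3 or BED annotation into a :class:`GenomeAnnotation`.

    GFF3: only records of type ``gene`` are retained (the analysis is
    gene-order based; mRNA/CDS features are ignored).  The gene id is the
    ``ID`` attribute.  BED: 6-column, every record is a gene, name column
    is the gene id; BED starts are converted from 0-based to 1-based.
    """
    path = Path(path)
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    gid = genome_id if genome_id is not None else path.stem
    records: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if format == "gff3":
                if len(line.split("\t")) != 9:
                    raise AnnotationError(
                        f"{path}:{lineno}: GFF3 line does not have 9 fields"
                    )
                try:
                    feat = feature_from_line(line)
                except Exception as exc:
                    raise AnnotationError(
                        f"{path}:{lineno}: unparseable GFF3 line ({exc})"
                    ) from exc
                if feat.featuretype != "gene":
                    continue
                ids = feat.attributes.get("ID")
                if not ids:
                    raise AnnotationError(f"{path}:{lineno}: gene record without ID")
                records.append(
                    (ids[0], feat.seqid, feat.start, feat.end, feat.strand)
                )
            else:
                fields = line.split("\t")
                if len(fields) < 6:
                    raise AnnotationError(
                        f"{path}:{lineno}: BED record has {len(fields)} fields, "
                        "expected 6"
                    )
                try:
                    start0, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise AnnotationError(
                        f"{path}:{lineno}: non-integer BED coordinates"
                    ) from exc
                records.append((fields[3], fields[0], start0 + 1, end, fields[5]))
    if not records:
        raise AnnotationError(f"{path}: no gene records found")
    return GenomeAnnotation.from_records(gid, records)


def write_gene_annotations(
    genome: GenomeAnnotation, path: str | Path, format: str
) -> None:
    """Write annotations as GFF3 gene records or 6-column BED."""
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            for g in genome.chromosome_genes(chrom):
                if format == "gff3":
                    fh.write(
                        f"{g.chromosome}\twgdsig\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}\n"
                    )
                else:
                    fh.write(
                        f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t"
                        f"{g.strand}\n"
                    )


# ---------------------------------------------------------------------------
# homolog pairs


def read_homolog_pairs(path: str | Path) -> list[HomologPair]:
    """Read a homolog TSV (target_gene, reference_gene, similarity).

    Lines starting with ``#`` are headers/comments and skipped.  Gene ids
    are *not* resolved against annotations here; that happens at chaining
    time so one table can be reused with re-read annotations.
    """
    pairs: list[HomologPair] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                sim = float(row[2])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: similarity {row[2]!r} is not a number"
                ) from exc
            if not 0.0 <= sim <= 100.0:
                raise AnnotationError(
                    f"{path}:{lineno}: similarity {sim} outside [0, 100]"
                )
            pairs.append(HomologPair(row[0], row[1], sim))
    return pairs


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#target_gene\treference_gene\tsimilarity\n")
        for p in pairs:
            fh.write(f"{p.target_gene}\t{p.reference_gene}\t{p.similarity:g}\n")


# ---------------------------------------------------------------------------
# DAGchainer-dialect syntenic blocks

_DAG_HEADER = "## {tchr} vs {rchr} {orient} block {k} (num aligned pairs: {n})"


def write_dagchainer_blocks(blocks, path: str | Path, target, reference) -> None:
    """Write blocks in the DAGchainer-style text dialect.

    One ``##`` header per block followed by one tab-separated anchor line
    per homolog pair: target chromosome, target gene, target start/end,
    reference chromosome, reference gene, reference start/end, similarity.
    """
    t_by_ord = {
        (g.chromosome, g.ordinal): g for g in target.genes.values()
    }
    r_by_ord = {
        (g.chromosome, g.ordinal): g for g in reference.genes.values()
    }
    with open(path, "w") as fh:
        for b in blocks:
            orient = "f" if b.orientation == "parallel" else "r"
            fh.write(
                _DAG_HEADER.format(
                    tchr=b.target_chromosome,
                    rchr=b.reference_chromosome,
                    orient=orient,
                    k=b.block_id,
                    n=len(b.anchors),
                )
                + "\n"
            )
            for a in b.anchors:
                tg = t_by_ord[(b.target_chromosome, a.target_ordinal)]
                rg = r_by_ord[(b.reference_chromosome, a.reference_ordinal)]
                fh.write(
                    f"{tg.chromosome}\t{tg.gene_id}\t{tg.start}\t{tg.end}\t"
                    f"{rg.chromosome}\t{rg.gene_id}\t{rg.start}\t{rg.end}\t"
                    f"{a.similarity:g}\n"
                )


def read_dagchainer_blocks(
    path: str | Path,
    target: GenomeAnnotation,
    reference: GenomeAnnotation,
) -> list:
    """Read DAGchainer-style block text into :class:`SyntenicBlock` objects.

    Each ``#`` header starts a new block group; anchor lines carry the
    target gene in column 2 and the reference gene in column 6 (the layout
    :func:`write_dagchainer_blocks` emits).  Anchor genes are mapped to
    ordinals via the annotations; an unknown gene is a hard error.  Empty
    header groups are skipped with a warning.
    """
    import logging

    from .synteny import AnchorPair, SyntenicBlock, _block_from_anchors

    log = logging.getLogger(__name__)
    groups: list[list[str]] = []
    with open(path) as fh:
        current: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if current is not None and not current:
                    log.warning("empty block group in %s; skipped", path)
                current = []
                groups.append(current)
            elif current is not None:
                current.append(line)
            else:
                raise AnnotationError(f"{path}: anchor line before any block header")
    blocks: list[SyntenicBlock] = []
    counter: Counter[tuple[str, str]] = Counter()
    for group in groups:
        if not group:
            log.warning("empty block group in %s; skipped", path)
            continue
        anchors: list[AnchorPair] = []
        tchr = rchr = None
        for line in group:
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}: anchor line has {len(fields)} fields, expected >=6"
                )
            tgid, rgid = fields[1], fields[5]
            if tgid not in target.genes:
                raise AnnotationError(
                    f"{path}: anchor gene {tgid!r} not in target annotation"
                )
            if rgid not in reference.genes:
                raise AnnotationError(
                    f"{path}: anchor gene {rgid!r} not in reference annotation"
                )
            tg, rg = target.genes[tgid], reference.genes[rgid]
            tchr, rchr = tg.chromosome, rg.chromosome
            sim = float(fields[8]) if len(fields) > 8 else 0.0
            anchors.append(AnchorPair(tg.ordinal, rg.ordinal, sim))
        anchors.sort(key=lambda a: (a.target_ordinal, a.reference_ordinal))
        counter[(tchr, rchr)] += 1
        block_id = f"{tchr}_{rchr}_{counter[(tchr, rchr)]}"
        blocks.append(_block_from_anchors(block_id, tchr, rchr, anchors))
    return blocks


# ---------------------------------------------------------------------------
# similarity histogram


def similarity_distribution(
    pairs: Iterable[HomologPair], bin_width: float
) -> dict[float, int]:
    """Histogram of pair similarities over [0, 100].

    Bins are half-open ``[lo, lo + bin_width)`` except the top bin, which
    is closed so a similarity of exactly 100 is representable.  Returns a
    mapping of occupied bin lower edges to counts; empty input gives an
    empty mapping.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    import math

    n_bins = math.ceil(100.0 / bin_width)
    last_lo = (n_bins - 1) * bin_width
    counts: dict[float, int] = {}
    for p in pairs:
        lo = math.floor(p.similarity / bin_width) * bin_width
        if lo > last_lo:
            lo = last_lo
        counts[lo] = counts.get(lo, 0) + 1
    return counts
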