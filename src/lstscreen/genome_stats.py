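"""Assembly statistics and gene-structure statistics.

N50 follows the scaffold-based definition: the length of the shortest
sequence in the smallest set of longest sequences whose summed length
reaches half the assembly.  GC is computed over unambiguous A/C/G/T only.
Gene models come from GFF3; multi-isoform genes are represented by the
isoform with the most exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .hits import GeneAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    gc_pct: float
    n_scaffolds: int
    max_len: int
    min_len: int
    n50: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    protein_length: int

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def compute_n50(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if 2 * running >= total:
            return length
    raise ValueError("empty length set")


def assembly_stats(fasta: str | Path) -> AssemblyStats:
    lengths = []
    gc = 0
    at = 0
    for record in SeqIO.parse(str(fasta), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"zero-length record {record.id}")
        lengths.append(len(seq))
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if not lengths:
        raise ValueError(f"no sequences in {fasta}")
    denom = gc + at
    return AssemblyStats(
        total_bp=sum(lengths),
        gc_pct=100.0 * gc / denom if denom else float("nan"),
        n_scaffolds=len(lengths),
        max_len=max(lengths),
        min_len=min(lengths),
        n50=compute_n50(lengths),
    )


def scaffold_lengths(fasta: str | Path) -> dict[str, int]:
    return {record.id: len(record.seq) for record in SeqIO.parse(str(fasta), "fasta")}


def parse_gene_models(gff3: str | Path) -> list[GeneModel]:
    """One GeneModel per gene feature, 1-based inclusive coordinates.

    Exon structure is taken from CDS features (exon features used when a
    transcript has no CDS); protein length is the summed CDS length in
    codons minus the stop.
    """
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        best_exons: list[tuple[int, int]] | None = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = [
                (f.start, f.end)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            if not exons:
                exons = [
                    (f.start, f.end)
                    for f in db.children(mrna, featuretype="exon", order_by="start")
                ]
            if exons and (best_exons is None or len(exons) > len(best_exons)):
                best_exons = exons
        if best_exons is None:
            logger.warning("gene %s has no exon/CDS features; skipped", gene.id)
            continue
        for start, end in best_exons:
            if end < start:
                raise ValueError(f"gene {gene.id}: interval end {end} < start {start}")
        cds_bp = sum(end - start + 1 for start, end in best_exons)
        models.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(sorted(best_exons)),
                protein_length=max(cds_bp // 3 - 1, 0),
            )
        )
    return models


def gene_catalog(models: Sequence[GeneModel]) -> dict[str, str]:
    """gene id -> scaffold id mapping used by assignment."""
    return {m.gene_id: m.scaffold_id for m in models}


def attach_intron_counts(
    assignments: Sequence[GeneAssignment], models: Sequence[GeneModel]
) -> list[GeneAssignment]:
    by_gene = {m.gene_id: m.intron_count for m in models}
    from dataclasses import replace

    return [replace(a, intron_count=by_gene.get(a.gene_id)) for a in assignments]


def default_intron_grouping(assignment: GeneAssignment) -> str | None:
    """Paper-style contrast: bacteria+archaea vs giant viruses vs everything."""
    if assignment.donor is None:
        return None
    if assignment.donor.is_giant_virus:
        return "giant_virus"
    if assignment.donor.superkingdom in ("Bacteria", "Archaea"):
        return "bacteria_archaea"
    return None


def mean_introns_by_group(
    models: Sequence[GeneModel],
    assignments: Sequence[GeneAssignment],
    grouping: Callable[[GeneAssignment], str | None] = default_intron_grouping,
) -> dict[str, float]:
    """Arithmetic mean introns/gene per group; also reports an ``all`` group.

    Groups with zero genes are absent from the result.  Means are returned at
    full precision; report writers round to one decimal.
    """
    introns: Mapping[str, int] = {m.gene_id: m.intron_count for m in models}
    by_assignment = {a.gene_id: a for a in assignments}
    sums: dict[str, list[float]] = {}
    for gene_id, count in introns.items():
        sums.setdefault("all", []).append(count)
        assignment = by_assignment.get(gene_id)
        if assignment is None:
            continue
        group = grouping(assignment)
        if group is not None:
            sums.setdefault(group, []).append(count)
    return {group: sum(vals) / len(vals) for group, vals in sums.items()}


def length_filter_stats(
    models: Sequence[GeneModel], min_aa: int = 100
) -> tuple[int, float | None]:
    """(count of genes with protein >= min_aa, proportion or None if empty)."""
    if not models:
        return 0, None
    count = sum(1 for m in models if m.protein_length >= min_aa)
    return count, count / len(models)
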