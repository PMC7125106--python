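"""Tabular homology-hit parsing, e-value filtering, best-hit selection and
per-gene donor assignment (ORFan calling included).

Input is the standard 12-column tabular search format extended with a 13th
column holding the subject taxon id.  Best hits maximize bitscore with
deterministic tie-breaking (smaller e-value, then lexicographically smallest
subject id), so assignment is invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .taxonomy import DonorGroup, GroupConfig, TaxonomyTree, classify

logger = logging.getLogger(__name__)

#: Default e-value cutoff; the boundary is inclusive.
DEFAULT_MAX_EVALUE = 1e-3


class HitParseError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_taxid: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}")
        if self.aln_len < 1:
            raise ValueError(f"alignment length < 1 for {self.query_id}")


@dataclass(frozen=True)
class GeneAssignment:
    """Per-gene screening outcome.

    ``status`` is ``"ORFan"`` exactly when no hit survived filtering; a donor
    group and organism name are present exactly when the gene is assigned.
    """

    gene_id: str
    scaffold_id: str
    status: str
    best_hit: HitRecord | None = None
    donor: DonorGroup | None = None
    organism: str | None = None
    expressed: bool | None = None
    read_count: int | None = None
    intron_count: int | None = None

    def __post_init__(self) -> None:
        if (self.status == "ORFan") != (self.best_hit is None):
            raise ValueError("ORFan status must coincide with absent best hit")
        if (self.status == "Assigned") != (self.donor is not None):
            raise ValueError("donor present iff status Assigned")

    def with_expression(self, read_count: int, min_reads: int) -> "GeneAssignment":
        return replace(self, read_count=read_count, expressed=read_count >= min_reads)


def parse_hits(path: str | Path) -> Iterator[HitRecord]:
    """Stream hit records from a 13-column tabular file, preserving order."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 13:
                raise HitParseError(
                    f"{path}:{lineno}: expected 13 columns, got {len(fields)}"
                )
            try:
                yield HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_taxid=int(fields[12]),
                )
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc


def filter_hits(
    records: Iterable[HitRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    self_taxids: frozenset[int] | set[int] = frozenset(),
) -> Iterator[HitRecord]:
    """Keep records with evalue <= max_evalue whose subject is not a self taxon."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    for record in records:
        if record.evalue <= max_evalue and record.subject_taxid not in self_taxids:
            yield record


def best_hit(records: Iterable[HitRecord]) -> HitRecord:
    """Argmax by bitscore; ties by smaller e-value, then subject id."""
    best = None
    for record in records:
        if best is None:
            best = record
            continue
        key = (-record.bitscore, record.evalue, record.subject_id)
        best_key = (-best.bitscore, best.evalue, best.subject_id)
        if key < best_key:
            best = record
    if best is None:
        raise ValueError("best_hit on empty record set")
    return best


def hits_by_query(records: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for record in records:
        grouped.setdefault(record.query_id, []).append(record)
    return grouped


def assign_genes(
    hits_by_gene: Mapping[str, list[HitRecord]],
    gene_catalog: Mapping[str, str],
    tree: TaxonomyTree,
    group_config: GroupConfig,
) -> list[GeneAssignment]:
    """Assign every catalog gene: ORFan when no surviving hits, otherwise the
    best hit's donor group.  ``gene_catalog`` maps gene id -> scaffold id.

    A hit for a gene absent from the catalog is an error (it signals a
    mismatched gene-model/hit-table pair, not missing data).
    """
    unknown = set(hits_by_gene) - set(gene_catalog)
    if unknown:
        raise KeyError(
            f"{len(unknown)} hit quer{'y' if len(unknown) == 1 else 'ies'} absent "
            f"from gene catalog, e.g. {sorted(unknown)[:3]}"
        )
    assignments = []
    for gene_id, scaffold_id in gene_catalog.items():
        gene_hits = hits_by_gene.get(gene_id, [])
        if not gene_hits:
            assignments.append(GeneAssignment(gene_id, scaffold_id, "ORFan"))
            continue
        hit = best_hit(gene_hits)
        donor = classify(tree, hit.subject_taxid, group_config)
        assignments.append(
            GeneAssignment(
                gene_id,
                scaffold_id,
                "Assigned",
                best_hit=hit,
                donor=donor,
                organism=tree.name_of(hit.subject_taxid),
            )
        )
    logger.info(
        "assigned %d genes: %d ORFan, %d with best hits",
        len(assignments),
        sum(1 for a in assignments if a.status == "ORFan"),
        sum(1 for a in assignments if a.status == "Assigned"),
    )
    return assignments


def write_assignments(assignments: Iterable[GeneAssignment], path: str | Path) -> None:
    """Per-gene assignment TSV with header."""
    header = (
        "gene_id\tscaffold\tstatus\tsubject_id\tevalue\tbitscore\t"
        "superkingdom\tsubgroup\tflags\torganism\tread_count\texpressed\tintron_count"
    )
    with open(path, "w") as out:
        out.write(header + "\n")
        for a in assignments:
            if a.status == "Assigned":
                flags = "cpr" if a.donor.is_cpr else ("giant_virus" if a.donor.is_giant_virus else "-")
                hit_cols = (
                    f"{a.best_hit.subject_id}\t{a.best_hit.evalue:.3g}\t"
                    f"{a.best_hit.bitscore:.1f}\t{a.donor.superkingdom}\t"
                    f"{a.donor.subgroup or ''}\t{flags}\t{a.organism or ''}"
                )
            else:
                hit_cols = "\t\t\t\t\t\t"
            out.write(
                f"{a.gene_id}\t{a.scaffold_id}\t{a.status}\t{hit_cols}\t"
                f"{'' if a.read_count is None else a.read_count}\t"
                f"{'' if a.expressed is None else int(a.expressed)}\t"
                f"{'' if a.intron_count is None else a.intron_count}\n"
            )
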