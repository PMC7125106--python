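"""Contaminant-scaffold exclusion.

A scaffold is flagged as a bacterial contaminant when *every* gene it
carries is assigned, every best hit is bacterial, and all best-hit taxa
collapse to the same ancestor at a configurable rank (species by default).
Single-gene scaffolds satisfy the rule literally and are excluded unless
``min_genes`` is raised; verdicts record the shared taxon so flagged
scaffolds can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .hits import GeneAssignment
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaffoldVerdict:
    scaffold_id: str
    n_genes: int
    verdict: str  # "kept" | "excluded"
    contaminant_taxid: int | None = None

    def __post_init__(self) -> None:
        if self.verdict == "excluded" and (self.contaminant_taxid is None or self.n_genes < 1):
            raise ValueError("excluded verdict requires a contaminant taxid and >= 1 gene")


def flag_contaminants(
    assignments: Sequence[GeneAssignment],
    tree: TaxonomyTree,
    rank: str = "species",
    min_genes: int = 1,
) -> list[ScaffoldVerdict]:
    """One verdict per scaffold, in sorted scaffold-id order."""
    by_scaffold: dict[str, list[GeneAssignment]] = {}
    for assignment in assignments:
        by_scaffold.setdefault(assignment.scaffold_id, []).append(assignment)

    verdicts = []
    for scaffold_id in sorted(by_scaffold):
        genes = by_scaffold[scaffold_id]
        verdicts.append(_judge(scaffold_id, genes, tree, rank, min_genes))
    n_excluded = sum(1 for v in verdicts if v.verdict == "excluded")
    logger.info(
        "contamination filter: %d/%d scaffolds flagged at rank %s",
        n_excluded,
        len(verdicts),
        rank,
    )
    return verdicts


def _judge(
    scaffold_id: str,
    genes: Sequence[GeneAssignment],
    tree: TaxonomyTree,
    rank: str,
    min_genes: int,
) -> ScaffoldVerdict:
    if len(genes) < min_genes:
        return ScaffoldVerdict(scaffold_id, len(genes), "kept")
    shared: int | None = None
    for gene in genes:
        if gene.status != "Assigned" or gene.donor.superkingdom != "Bacteria":
            return ScaffoldVerdict(scaffold_id, len(genes), "kept")
        taxid = gene.best_hit.subject_taxid
        ancestor = tree.ancestor_at_rank(taxid, rank) if taxid in tree else None
        group = ancestor.taxid if ancestor is not None else taxid
        if shared is None:
            shared = group
        elif group != shared:
            return ScaffoldVerdict(scaffold_id, len(genes), "kept")
    return ScaffoldVerdict(scaffold_id, len(genes), "excluded", contaminant_taxid=shared)


def apply_verdicts(
    assignments: Sequence[GeneAssignment],
    verdicts: Iterable[ScaffoldVerdict],
) -> tuple[list[GeneAssignment], int]:
    """Drop genes on excluded scaffolds; returns (kept, n_removed).

    Every scaffold in ``assignments`` must carry a verdict.
    """
    verdict_map = {v.scaffold_id: v.verdict for v in verdicts}
    missing = {a.scaffold_id for a in assignments} - set(verdict_map)
    if missing:
        raise KeyError(f"no verdict for scaffolds: {sorted(missing)[:5]}")
    kept = [a for a in assignments if verdict_map[a.scaffold_id] == "kept"]
    removed = len(assignments) - len(kept)
    if not kept and assignments:
        logger.warning("every scaffold excluded as contaminant; empty assignment set")
    logger.info("contamination filter removed %d of %d genes", removed, len(assignments))
    return kept, removed
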