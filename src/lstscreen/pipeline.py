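"""End-to-end screen: parse inputs, assign donors, filter contaminants,
attach expression and intron counts, tally, and write reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import contamination, expression, genome_stats, hits, rhizome, taxonomy

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    assignments: list[hits.GeneAssignment]  # post-filter, with expression/introns
    all_assignments: list[hits.GeneAssignment]  # pre-contamination-filter
    verdicts: list[contamination.ScaffoldVerdict]
    n_contaminant_genes: int
    tally: rhizome.DonorTally
    assembly: genome_stats.AssemblyStats
    models: list[genome_stats.GeneModel]
    intron_means: dict[str, float]
    report: dict


def run_screen(
    fasta: str | Path,
    gff3: str | Path,
    hit_table: str | Path,
    counts_table: str | Path,
    node_table: str | Path,
    name_table: str | Path,
    group_config: taxonomy.GroupConfig | None = None,
    self_taxids: Sequence[int] = (),
    max_evalue: float = hits.DEFAULT_MAX_EVALUE,
    min_reads: int = expression.DEFAULT_MIN_READS,
    contaminant_rank: str = "species",
    min_contaminant_genes: int = 1,
    outdir: str | Path | None = None,
) -> ScreenResult:
    config = group_config or taxonomy.GroupConfig.default()
    tree = taxonomy.load_taxonomy(node_table, name_table)
    logger.info("taxonomy: %d nodes", len(tree))

    models = genome_stats.parse_gene_models(gff3)
    catalog = genome_stats.gene_catalog(models)
    logger.info("gene catalog: %d genes", len(catalog))

    raw = hits.parse_hits(hit_table)
    surviving = hits.filter_hits(raw, max_evalue=max_evalue, self_taxids=set(self_taxids))
    grouped = hits.hits_by_query(surviving)
    assignments = hits.assign_genes(grouped, catalog, tree, config)

    verdicts = contamination.flag_contaminants(
        assignments, tree, rank=contaminant_rank, min_genes=min_contaminant_genes
    )
    kept, n_removed = contamination.apply_verdicts(assignments, verdicts)

    counts = expression.load_counts(counts_table)
    kept = expression.flag_transcribed(kept, counts, min_reads=min_reads)
    kept = genome_stats.attach_intron_counts(kept, models)

    assembly = genome_stats.assembly_stats(fasta)
    donor_tally = rhizome.tally(kept)
    kept_ids = {a.gene_id for a in kept}
    kept_models = [m for m in models if m.gene_id in kept_ids]
    intron_means = genome_stats.mean_introns_by_group(kept_models, kept)
    length_stats = genome_stats.length_filter_stats(kept_models)
    report = rhizome.summary_report(
        donor_tally,
        assembly=assembly,
        length_filter=(length_stats[0], len(kept_models)),
        intron_means=intron_means,
        n_contaminant_genes=n_removed,
        n_contaminant_scaffolds=sum(1 for v in verdicts if v.verdict == "excluded"),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hits.write_assignments(kept, outdir / "assignments.tsv")
        rhizome.write_summary(report, outdir / "summary.json", outdir / "summary.tsv")
        lengths = genome_stats.scaffold_lengths(fasta)
        intervals = {m.gene_id: m.span for m in models}
        rhizome.write_rhizome(
            kept,
            lengths,
            donor_filter=lambda d: d.is_giant_virus,
            karyotype_path=outdir / "rhizome_karyotype.txt",
            links_path=outdir / "rhizome_links.txt",
            gene_intervals=intervals,
        )
        candidates = expression.rank_expressed(
            kept, donor_filter=lambda d: d.superkingdom in ("Bacteria", "Viruses")
        )
        expression.write_candidate_report(candidates, outdir / "expressed_candidates.tsv")
        with open(outdir / "scaffold_verdicts.tsv", "w") as out:
            out.write("scaffold_id\tn_genes\tverdict\tcontaminant_taxid\n")
            for v in verdicts:
                out.write(
                    f"{v.scaffold_id}\t{v.n_genes}\t{v.verdict}\t"
                    f"{'' if v.contaminant_taxid is None else v.contaminant_taxid}\n"
                )

    return ScreenResult(
        assignments=kept,
        all_assignments=assignments,
        verdicts=verdicts,
        n_contaminant_genes=n_removed,
        tally=donor_tally,
        assembly=assembly,
        models=models,
        intron_means=intron_means,
        report=report,
    )
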