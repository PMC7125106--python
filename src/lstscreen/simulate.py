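"""Synthetic input bundles with planted ground truth.

Generates every file the screening pipeline consumes — taxonomy tables, a
scaffolded genome FASTA, GFF3 gene models, a 13-column hit table, a counts
TSV — together with a per-gene truth table, so every stage can be tested
against known planted origins without any external data.

Sequences are random-composition: nothing downstream of hit fabrication
depends on residue content.  Fabricated e-values decay with bitscore and
carry multiplicative noise so the e-value filter and best-hit tie-breaking
are actually exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import ProteinAlignment, SupportTree
from .taxonomy import TaxonNode, TaxonomyTree, write_taxonomy

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: Origin classes drawn for each simulated gene.
ORIGIN_CLASSES = (
    "eukaryote",
    "amoebozoa",
    "bacteria",
    "cpr",
    "archaea",
    "giant_virus",
    "orfan",
)

SUPERKINGDOM_OF_CLASS = {
    "eukaryote": "Eukaryota",
    "amoebozoa": "Eukaryota",
    "bacteria": "Bacteria",
    "cpr": "Bacteria",
    "archaea": "Archaea",
    "giant_virus": "Viruses",
    "contaminant": "Bacteria",
}


def _paper_like_proportions() -> dict[str, float]:
    # echoes the published taxonomy shares: ~56% eukaryote (19.8% Amoebozoa
    # within), ~10% bacteria, ~0.6% archaea, ~0.8% giant virus, ~32% ORFan
    return {
        "eukaryote": 0.361,
        "amoebozoa": 0.198,
        "bacteria": 0.1007,
        "cpr": 0.0013,
        "archaea": 0.006,
        "giant_virus": 0.008,
        "orfan": 0.325,
    }


def _paper_like_intron_means() -> dict[str, float]:
    return {
        "eukaryote": 3.5,
        "amoebozoa": 3.5,
        "orfan": 3.5,
        "bacteria": 2.7,
        "cpr": 2.7,
        "archaea": 2.7,
        "contaminant": 2.7,
        "giant_virus": 1.4,
    }


@dataclass
class SimulationConfig:
    seed: int
    n_scaffolds: int = 100
    mean_genes_per_scaffold: float = 5.0  # scaffolds always carry >= 2 genes
    origin_proportions: dict[str, float] = field(default_factory=_paper_like_proportions)
    noise_eps: float = 0.0
    n_contaminant_scaffolds: int = 0
    contaminant_genes_per_scaffold: int = 4
    intron_means: dict[str, float] = field(default_factory=_paper_like_intron_means)
    counts_zero_inflation: float = 0.5
    counts_mean: float = 20.0
    gc_content: float = 0.417
    self_hit_rate: float = 0.05

    def __post_init__(self) -> None:
        if set(self.origin_proportions) != set(ORIGIN_CLASSES):
            raise ValueError(f"origin_proportions must cover {ORIGIN_CLASSES}")
        total = sum(self.origin_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin proportions sum to {total}, not 1")
        if any(v < 0 for v in self.origin_proportions.values()):
            raise ValueError("origin proportions must be >= 0")
        if any(v < 0 for v in self.intron_means.values()):
            raise ValueError("intron means must be >= 0")
        if not 0 <= self.noise_eps <= 1:
            raise ValueError("noise_eps must be a probability")
        if self.mean_genes_per_scaffold < 2:
            raise ValueError("mean_genes_per_scaffold must be >= 2")


@dataclass
class SimulationBundle:
    """Paths of the generated files plus in-memory objects for tests."""

    outdir: Path
    node_table: Path
    name_table: Path
    fasta: Path
    gff3: Path
    hits: Path
    counts: Path
    truth_table: Path
    tree: TaxonomyTree
    truth: pd.DataFrame
    self_taxid: int
    config: SimulationConfig


def build_synthetic_taxonomy() -> tuple[TaxonomyTree, dict[str, list[int]], int]:
    """Small deterministic taxonomy mirroring the donor-group scheme.

    Returns (tree, species taxids per origin class, self taxid).
    """
    nodes: list[TaxonNode] = [TaxonNode(1, 1, "no_rank", "root")]
    next_id = [2]

    def add(parent: int, rank: str, name: str) -> int:
        taxid = next_id[0]
        next_id[0] += 1
        nodes.append(TaxonNode(taxid, parent, rank, name))
        return taxid

    euk = add(1, "superkingdom", "Eukaryota")
    bac = add(1, "superkingdom", "Bacteria")
    arc = add(1, "superkingdom", "Archaea")
    vir = add(1, "superkingdom", "Viruses")

    species: dict[str, list[int]] = {k: [] for k in ORIGIN_CLASSES if k != "orfan"}

    opistho = add(euk, "phylum", "Opisthokonta")
    for genus_name, spp in [
        ("Saccharomyces", ["Saccharomyces cerevisiae"]),
        ("Monosiga", ["Monosiga brevicollis"]),
        ("Capsaspora", ["Capsaspora owczarzaki"]),
    ]:
        genus = add(opistho, "genus", genus_name)
        for name in spp:
            species["eukaryote"].append(add(genus, "species", name))

    amoebozoa = add(euk, "phylum", "Amoebozoa")
    vermamoeba = add(amoebozoa, "genus", "Vermamoeba")
    self_taxid = add(vermamoeba, "species", "Vermamoeba vermiformis")
    acantha = add(amoebozoa, "genus", "Acanthamoeba")
    species["amoebozoa"].append(add(acantha, "species", "Acanthamoeba castellanii"))
    species["amoebozoa"].append(add(acantha, "species", "Acanthamoeba polyphaga"))
    dicty = add(amoebozoa, "genus", "Dictyostelium")
    species["amoebozoa"].append(add(dicty, "species", "Dictyostelium discoideum"))

    for phylum_name, genera in [
        (
            "Proteobacteria",
            [
                ("Sphingobium", ["Sphingobium ummariense", "Sphingobium japonicum"]),
                ("Salmonella", ["Salmonella enterica"]),
                ("Legionella", ["Legionella pneumophila"]),
            ],
        ),
        (
            "Bacteroidetes",
            [
                ("Solitalea", ["Solitalea canadensis"]),
                ("Chitinophaga", ["Chitinophagaceae bacterium PMP191F"]),
            ],
        ),
        ("Cyanobacteria", [("Synechococcus", ["Synechococcus elongatus", "Synechococcus sp. PCC"])]),
        ("Firmicutes", [("Bacillus", ["Bacillus subtilis", "Bacillus cereus"])]),
        ("Actinobacteria", [("Mycobacterium", ["Mycobacterium sp. YC-RL4", "Mycobacterium smegmatis"])]),
    ]:
        phylum = add(bac, "phylum", phylum_name)
        for genus_name, spp in genera:
            genus = add(phylum, "genus", genus_name)
            for name in spp:
                species["bacteria"].append(add(genus, "species", name))

    for cpr_name, spp in [
        ("Parcubacteria", ["Parcubacteria bacterium A", "Parcubacteria bacterium B"]),
        ("Microgenomates", ["Microgenomates bacterium A", "Microgenomates bacterium B"]),
        ("Peregrinibacteria", ["Peregrinibacteria bacterium A"]),
        ("Doudnabacteria", ["Doudnabacteria bacterium A"]),
        ("CPR2", ["CPR2 bacterium A"]),
    ]:
        phylum = add(bac, "phylum", cpr_name)
        for name in spp:
            species["cpr"].append(add(phylum, "species", name))

    eury = add(arc, "phylum", "Euryarchaeota")
    for name in ["Methanococcus maripaludis", "Haloferax volcanii"]:
        species["archaea"].append(add(eury, "species", name))

    megavirales = add(vir, "order", "Megavirales")
    mimi = add(megavirales, "family", "Mimiviridae")
    klosneu = add(mimi, "family", "Klosneuvirinae")
    for name in [
        "Bodo saltans virus",
        "Klosneuvirus KNV1",
        "Catovirus CTV1",
        "Hokovirus HKV1",
        "Indivirus ILV1",
    ]:
        species["giant_virus"].append(add(klosneu, "species", name))
    tupan = add(mimi, "genus", "Tupanvirus")
    for name in ["Tupanvirus deep ocean", "Tupanvirus soda lake"]:
        species["giant_virus"].append(add(tupan, "species", name))
    for genus_name, spp in [
        ("Orpheovirus", ["Orpheovirus IHUMI-LCC2"]),
        ("Faustovirus", ["Faustovirus E12", "Faustovirus D3"]),
        ("Kaumoebavirus", ["Kaumoebavirus Sc"]),
        ("Cedratvirus", ["Cedratvirus A11", "Cedratvirus lausannensis"]),
        ("Pandoravirus", ["Pandoravirus inopinatum"]),
    ]:
        genus = add(megavirales, "genus", genus_name)
        for name in spp:
            species["giant_virus"].append(add(genus, "species", name))
    phycodna = add(vir, "family", "Phycodnaviridae")
    for name in [
        "Acanthocystis turfacea Chlorella virus MN0810.1",
        "Phaeocystis globosa virus",
    ]:
        species["giant_virus"].append(add(phycodna, "species", name))
    # non-giant phages: classify as Other-virus
    add(vir, "species", "Ralstonia phage phiRSL1")
    add(vir, "species", "Synechococcus phage S-SKS1")

    return TaxonomyTree(nodes), species, self_taxid


INTRON_LEN = 50
INTERGENIC_LEN = 200


def simulate(config: SimulationConfig, outdir: str | Path) -> SimulationBundle:
    """Generate the full input bundle under ``outdir``; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree, species, self_taxid = build_synthetic_taxonomy()
    all_donor_species = sorted(taxid for spp in species.values() for taxid in spp)
    kingdom_species = {
        "Eukaryota": sorted(species["eukaryote"] + species["amoebozoa"]),
        "Bacteria": sorted(species["bacteria"] + species["cpr"]),
        "Archaea": sorted(species["archaea"]),
        "Viruses": sorted(species["giant_virus"]),
    }

    classes = list(ORIGIN_CLASSES)
    probs = np.array([config.origin_proportions[c] for c in classes])

    # ---- plant genes on scaffolds -------------------------------------
    scaffold_genes: list[tuple[str, bool, list[dict]]] = []
    gene_counter = 0
    for s in range(config.n_scaffolds):
        scaffold_id = f"scaffold_{s + 1:05d}"
        n_genes = 2 + rng.poisson(config.mean_genes_per_scaffold - 2)
        genes = []
        for _ in range(n_genes):
            gene_counter += 1
            origin = classes[rng.choice(len(classes), p=probs)]
            donor = (
                int(rng.choice(species[origin])) if origin != "orfan" else 0
            )
            genes.append({"gene_id": f"g{gene_counter}", "origin": origin, "donor": donor})
        scaffold_genes.append((scaffold_id, False, genes))
    # contaminant scaffolds: every gene best-matches the same bacterium
    bacteria_pool = sorted(species["bacteria"])
    for c in range(config.n_contaminant_scaffolds):
        scaffold_id = f"contam_{c + 1:04d}"
        donor = bacteria_pool[c % len(bacteria_pool)]
        genes = []
        for _ in range(config.contaminant_genes_per_scaffold):
            gene_counter += 1
            genes.append(
                {"gene_id": f"g{gene_counter}", "origin": "contaminant", "donor": donor}
            )
        scaffold_genes.append((scaffold_id, True, genes))

    # fix-up: a non-contaminant scaffold must never satisfy the exclusion
    # rule (all genes bacterial with the same species)
    for scaffold_id, is_contam, genes in scaffold_genes:
        if is_contam:
            continue
        if all(g["origin"] in ("bacteria", "cpr") for g in genes) and len(
            {g["donor"] for g in genes}
        ) == 1:
            g = genes[1]
            pool = [t for t in species[g["origin"]] if t != g["donor"]]
            g["donor"] = pool[0]

    # ---- gene structures, scaffold sequences, GFF3 --------------------
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    truth_rows = []
    fasta_path = outdir / "genome.fasta"
    gff_path = outdir / "genes.gff3"
    with open(fasta_path, "w") as fasta_out, open(gff_path, "w") as gff_out:
        gff_out.write("##gff-version 3\n")
        for scaffold_id, is_contam, genes in scaffold_genes:
            pos = INTERGENIC_LEN
            gff_rows = []
            for gene in genes:
                introns = int(rng.poisson(config.intron_means[gene["origin"]]))
                aa = int(rng.integers(60, 600))
                cds_nt = 3 * aa + 3
                n_exons = introns + 1
                exon_len = cds_nt // n_exons
                exon_lengths = [exon_len] * n_exons
                exon_lengths[0] += cds_nt - exon_len * n_exons
                strand = "+" if rng.random() < 0.5 else "-"
                exons = []
                cursor = pos + 1  # 1-based
                for length in exon_lengths:
                    exons.append((cursor, cursor + length - 1))
                    cursor += length + INTRON_LEN
                gene_end = exons[-1][1]
                gene.update(
                    introns=introns,
                    aa=aa,
                    start=exons[0][0],
                    end=gene_end,
                    strand=strand,
                    exons=exons,
                )
                gff_rows.append(gene)
                pos = gene_end + INTERGENIC_LEN
            scaffold_len = pos + INTERGENIC_LEN
            seq = alphabet[rng.choice(4, size=scaffold_len, p=base_probs)]
            fasta_out.write(f">{scaffold_id}\n")
            raw = seq.tobytes().decode("ascii")
            for i in range(0, len(raw), 80):
                fasta_out.write(raw[i : i + 80] + "\n")
            for gene in gff_rows:
                gid = gene["gene_id"]
                attrs = f"ID={gid}"
                gff_out.write(
                    f"{scaffold_id}\tsim\tgene\t{gene['start']}\t{gene['end']}\t.\t{gene['strand']}\t.\t{attrs}\n"
                )
                gff_out.write(
                    f"{scaffold_id}\tsim\tmRNA\t{gene['start']}\t{gene['end']}\t.\t{gene['strand']}\t.\tID={gid}.t1;Parent={gid}\n"
                )
                phase = 0
                for k, (start, end) in enumerate(gene["exons"], 1):
                    gff_out.write(
                        f"{scaffold_id}\tsim\texon\t{start}\t{end}\t.\t{gene['strand']}\t.\tID={gid}.t1.exon{k};Parent={gid}.t1\n"
                    )
                    gff_out.write(
                        f"{scaffold_id}\tsim\tCDS\t{start}\t{end}\t.\t{gene['strand']}\t{phase}\tID={gid}.t1.cds;Parent={gid}.t1\n"
                    )
                    phase = (3 - ((end - start + 1) - phase) % 3) % 3

    # ---- hit table ----------------------------------------------------
    hits_path = outdir / "hits.tsv"
    with open(hits_path, "w") as hits_out:
        hits_out.write(
            "# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend\t"
            "sstart\tsend\tevalue\tbitscore\tstaxid\n"
        )
        for scaffold_id, is_contam, genes in scaffold_genes:
            for gene in genes:
                if gene["origin"] == "orfan":
                    continue
                rows = []
                aa = gene["aa"]
                best_bits = float(rng.uniform(300, 500))
                best_taxid = gene["donor"]
                true_kingdom = SUPERKINGDOM_OF_CLASS[gene["origin"]]
                if not is_contam and rng.random() < config.noise_eps:
                    wrong = [k for k in kingdom_species if k != true_kingdom]
                    kingdom = wrong[int(rng.choice(len(wrong)))]
                    best_taxid = int(rng.choice(kingdom_species[kingdom]))
                    gene["noisy"] = True
                rows.append(_hit_row(rng, gene["gene_id"], best_taxid, best_bits, aa, best=True))
                n_decoys = int(rng.integers(0, 20))
                for _ in range(n_decoys):
                    if rng.random() < 0.01:
                        taxid = 999_999  # stale id absent from the taxonomy
                    else:
                        taxid = int(rng.choice(all_donor_species))
                    bits = float(rng.uniform(30, 250))
                    rows.append(_hit_row(rng, gene["gene_id"], taxid, bits, aa, best=False))
                if rng.random() < config.self_hit_rate:
                    rows.append(
                        _hit_row(rng, gene["gene_id"], self_taxid, 600.0, aa, best=True)
                    )
                order = rng.permutation(len(rows))
                for idx in order:
                    hits_out.write(rows[int(idx)])

    # ---- counts -------------------------------------------------------
    counts_path = outdir / "counts.tsv"
    all_genes = [g for _, _, genes in scaffold_genes for g in genes]
    for gene in all_genes:
        if rng.random() < config.counts_zero_inflation:
            gene["reads"] = 0
        else:
            gene["reads"] = int(rng.poisson(config.counts_mean))
    with open(counts_path, "w") as counts_out:
        for gene in all_genes:
            if gene["reads"] > 0:
                counts_out.write(f"{gene['gene_id']}\t{gene['reads']}\n")
        counts_out.write("__no_feature\t1234\n")
        counts_out.write("__ambiguous\t56\n")

    # ---- truth + taxonomy ---------------------------------------------
    for scaffold_id, is_contam, genes in scaffold_genes:
        for gene in genes:
            truth_rows.append(
                {
                    "gene_id": gene["gene_id"],
                    "scaffold_id": scaffold_id,
                    "origin_class": gene["origin"],
                    "donor_taxid": gene["donor"],
                    "is_contaminant_scaffold": is_contam,
                    "intron_count": gene["introns"],
                    "read_count": gene["reads"],
                    "best_hit_noisy": bool(gene.get("noisy", False)),
                }
            )
    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    node_table = outdir / "nodes.tsv"
    name_table = outdir / "names.tsv"
    write_taxonomy(tree, node_table, name_table)

    return SimulationBundle(
        outdir=outdir,
        node_table=node_table,
        name_table=name_table,
        fasta=fasta_path,
        gff3=gff_path,
        hits=hits_path,
        counts=counts_path,
        truth_table=truth_path,
        tree=tree,
        truth=truth,
        self_taxid=self_taxid,
        config=config,
    )


def _hit_row(
    rng: np.random.Generator,
    gene_id: str,
    taxid: int,
    bitscore: float,
    aa: int,
    best: bool,
) -> str:
    """One fabricated 13-column hit line; e-value decays with bitscore."""
    if best:
        evalue = 10.0 ** (-bitscore / 10.0)
    else:
        evalue = 10.0 ** (-bitscore / 10.0 + rng.normal(0, 2))
    pident = rng.uniform(25, 95)
    aln_len = max(30, int(aa * rng.uniform(0.5, 1.0)))
    mismatch = int(aln_len * (100 - pident) / 100)
    return (
        f"{gene_id}\tSYN_{taxid}_{int(rng.integers(1, 1000))}\t{pident:.1f}\t{aln_len}\t"
        f"{mismatch}\t{int(rng.integers(0, 5))}\t1\t{aln_len}\t1\t{aln_len}\t"
        f"{evalue:.3e}\t{bitscore:.1f}\t{taxid}\n"
    )


def random_tree(
    leaf_names: list[str], rng: np.random.Generator, min_len: float = 0.1, max_len: float = 2.0
) -> SupportTree:
    """Random binary topology with uniform branch lengths; additive by
    construction, so its leaf-to-leaf path distances feed NJ oracles."""
    from .phylo import TreeNode

    if len(leaf_names) < 3:
        raise ValueError("need >= 3 leaves")
    nodes = [TreeNode(name=name) for name in leaf_names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = TreeNode(
            children=[
                (nodes[i], float(rng.uniform(min_len, max_len))),
                (nodes[j], float(rng.uniform(min_len, max_len))),
            ]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    root = TreeNode(
        children=[(n, float(rng.uniform(min_len, max_len))) for n in nodes]
    )
    return SupportTree(root)


def simulate_alignment(
    donor_tree: str | SupportTree,
    query_placement: str | None,
    n_columns: int,
    sub_rate: float,
    seed: int,
) -> ProteinAlignment:
    """Evolve aligned protein sequences along a topology, sites independent.

    ``donor_tree`` is a newick string (or SupportTree); if ``query_placement``
    names a leaf, a new leaf ``query`` is grafted as its sister on a short
    branch.  Each edge substitutes each site with probability
    ``min(0.95, sub_rate * branch_length)`` (length 1 when absent).
    """
    if not 0 < sub_rate < 0.75:
        raise ValueError("sub_rate must be in (0, 0.75)")
    if n_columns < 50:
        raise ValueError("n_columns must be >= 50")
    newick = donor_tree.to_newick() if isinstance(donor_tree, SupportTree) else donor_tree
    tree = dendropy.Tree.get(data=newick, schema="newick")
    if query_placement is not None:
        target = next(
            (l for l in tree.leaf_node_iter() if l.taxon.label == query_placement), None
        )
        if target is None:
            raise KeyError(f"unknown placement leaf {query_placement!r}")
        original_len = target.edge.length if target.edge.length is not None else 1.0
        parent = target.parent_node
        junction = parent.new_child(edge_length=original_len / 2)
        parent.remove_child(target)
        junction.add_child(target)
        target.edge.length = original_len / 2
        taxon = tree.taxon_namespace.new_taxon("query")
        query_node = junction.new_child(edge_length=original_len / 4)
        query_node.taxon = taxon

    rng = np.random.default_rng(seed)
    root_seq = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=n_columns)]
    sequences: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = sequences[id(node.parent_node)]
        length = node.edge.length if node.edge.length is not None else 1.0
        p_sub = min(0.95, sub_rate * length)
        seq = parent_seq.copy()
        mutate = rng.random(n_columns) < p_sub
        n_mut = int(mutate.sum())
        if n_mut:
            current = seq[mutate]
            # draw replacements guaranteed different from the current residue
            offsets = rng.integers(1, len(AMINO_ACIDS), size=n_mut)
            idx_current = np.searchsorted(AMINO_ACIDS, current)
            seq[mutate] = AMINO_ACIDS[(idx_current + offsets) % len(AMINO_ACIDS)]
        sequences[id(node)] = seq
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    return ProteinAlignment(
        [l.taxon.label for l in leaves],
        [sequences[id(l)].tobytes().decode("ascii") for l in leaves],
    )
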