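# lstscreen

Lateral-sequence-transfer (LST) screening for draft eukaryote genomes.

Given a scaffolded assembly, predicted gene models, a tabular
protein-homology hit table (12 standard columns + subject taxon id), a
per-gene RNA-seq read-count table and a taxonomy dump, `lstscreen`:

- assigns each predicted gene its **best homology hit** (bitscore argmax
  with deterministic tie-breaking) after an inclusive e-value filter
  (default `1e-3`) and self-taxon exclusion, calling genes with no
  surviving hit **ORFans**;
- maps best hits onto a **donor-group scheme** — superkingdom plus a
  subgroup label (Amoebozoa, bacterial phyla, Candidate Phyla Radiation
  groups, giant-virus lineages) driven by a plain-text marker config;
- excludes **contaminant scaffolds**: scaffolds on which *every* gene is
  assigned, bacterial, and best-matching the same species (rank
  configurable);
- attaches **expression support** (transcribed = covered by ≥ 5 reads,
  inclusive) and ranks expressed transfer candidates;
- computes **assembly statistics** (N50, GC over unambiguous bases) and
  **intron-density contrasts** by donor class;
- provides **tree-based congruence tests** for candidate transfers:
  p-distances with pairwise gap deletion, classical neighbor joining,
  column-resampling bootstrap, and a midpoint-rooted sister-clade verdict
  (NJ deliberately substitutes for maximum likelihood — it is
  self-contained and exactly testable on additive matrices);
- emits **donor tallies**, one-decimal report percentages, and Circos-style
  **rhizome** (genome-mosaicism) karyotype/link files;
- ships a **synthetic-data generator** (`lstscreen.simulate`) that
  fabricates every input with planted per-gene origins, contaminant
  scaffolds, per-class Poisson intron counts and zero-inflated read counts,
  so the whole pipeline is testable offline against known truth.

## CLI

Generate a synthetic bundle, then screen it:

```sh
lst-screen simulate --seed 7 --outdir sim/ --n-scaffolds 200 --contaminant-scaffolds 5
lst-screen run \
    --fasta sim/genome.fasta --gff3 sim/genes.gff3 \
    --hits sim/hits.tsv --counts sim/counts.tsv \
    --taxonomy-nodes sim/nodes.tsv --taxonomy-names sim/names.tsv \
    --outdir out/ --self-taxid 15
```

`out/` then contains `assignments.tsv` (per-gene outcome),
`summary.json`/`summary.tsv` (headline counts and shares),
`scaffold_verdicts.tsv`, `expressed_candidates.tsv`, and
`rhizome_karyotype.txt` + `rhizome_links.txt` (giant-virus links by
default). `--evalue`, `--min-reads`, `--contaminant-rank` and `--config`
(donor-group marker TSV) override the defaults.

## Input formats

- **Hits**: tab-separated, 13 columns — the 12 standard tabular search
  columns (query, subject, %identity, length, mismatches, gap opens,
  q.start, q.end, s.start, s.end, e-value, bitscore) plus subject taxid;
  `#` lines ignored.
- **Taxonomy**: two TSVs — nodes `taxid<TAB>parent<TAB>rank` (root is its
  own parent; ranks restricted to superkingdom/phylum/class/order/family/
  genus/species/no_rank) and names `taxid<TAB>name`.
- **Counts**: `gene_id<TAB>count`; rows starting `__` (counter summaries)
  are skipped; genes absent from the table count as zero.
- **Donor-group config**: `marker_name<TAB>subgroup<TAB>flags` with flags
  `cpr`, `giant_virus` or `-`; the packaged default
  (`src/lstscreen/data/donor_groups.tsv`) encodes the CPR groups and
  giant-virus lineages, with tupanviruses kept outside Klosneuvirinae.
- **GFF3**: 1-based inclusive; multi-isoform genes are represented by the
  isoform with the most exons.
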