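"""Donor tallies, report percentages, COG tallies and rhizome export.

Percentages follow the report convention used throughout the screen:
``100 * n / d`` rounded half away from zero to one decimal.  Rhizome output
is a pair of Circos-style text files — a karyotype of the scaffolds that
carry selected genes plus one donor band per subgroup, and a links file
connecting each selected gene interval to a unit slot on its donor band.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .hits import GeneAssignment
from .taxonomy import DonorGroup

logger = logging.getLogger(__name__)


@dataclass
class DonorTally:
    """Gene counts at three grouping levels plus ORFan/total bookkeeping."""

    total_genes: int = 0
    n_orfan: int = 0
    by_superkingdom: Counter = field(default_factory=Counter)
    by_subgroup: Counter = field(default_factory=Counter)  # (superkingdom, subgroup)
    by_organism: Counter = field(default_factory=Counter)  # (superkingdom, subgroup, organism)

    @property
    def total_bacterial(self) -> int:
        return self.by_superkingdom.get("Bacteria", 0)

    def cpr_total(self) -> int:
        return sum(
            count
            for (_, subgroup), count in self.by_subgroup.items()
            if subgroup in self._cpr_subgroups
        )

    def giant_virus_total(self) -> int:
        return sum(
            count
            for (_, subgroup), count in self.by_subgroup.items()
            if subgroup in self._gv_subgroups
        )

    def __post_init__(self) -> None:
        self._cpr_subgroups: set[str] = set()
        self._gv_subgroups: set[str] = set()


def tally(assignments: Sequence[GeneAssignment]) -> DonorTally:
    out = DonorTally()
    for a in assignments:
        out.total_genes += 1
        if a.status == "ORFan":
            out.n_orfan += 1
            continue
        donor = a.donor
        out.by_superkingdom[donor.superkingdom] += 1
        out.by_subgroup[(donor.superkingdom, donor.subgroup)] += 1
        out.by_organism[(donor.superkingdom, donor.subgroup, a.organism or "?")] += 1
        if donor.is_cpr:
            out._cpr_subgroups.add(donor.subgroup)
        if donor.is_giant_virus:
            out._gv_subgroups.add(donor.subgroup)
    return out


def pct(numerator: int, denominator: int) -> float:
    """100*n/d rounded half away from zero to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("pct with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cog_tally(
    categories: Mapping[str, str], assignments: Sequence[GeneAssignment]
) -> dict[str, int]:
    """Counts per single-letter COG category plus an ``unassigned`` bucket.

    A gene annotated with several letters counts once per letter; letters
    outside A-Z are warned about and bucketed under ``other``.
    """
    counts: Counter = Counter()
    unassigned = 0
    for a in assignments:
        letters = categories.get(a.gene_id, "")
        if not letters:
            unassigned += 1
            continue
        for letter in letters:
            if not ("A" <= letter <= "Z"):
                logger.warning("unknown COG category %r for gene %s", letter, a.gene_id)
                counts["other"] += 1
            else:
                counts[letter] += 1
    result = dict(sorted(counts.items()))
    result["unassigned"] = unassigned
    return result


def write_rhizome(
    assignments: Sequence[GeneAssignment],
    scaffold_lengths: Mapping[str, int],
    donor_filter: Callable[[DonorGroup], bool],
    karyotype_path: str | Path,
    links_path: str | Path,
    gene_intervals: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[int, int]:
    """Write karyotype + links files; returns (n_links, n_scaffolds_with_links).

    ``gene_intervals`` maps gene id -> 1-based inclusive (start, end) on its
    scaffold; genes without an interval occupy a unit slot in gene order.
    Output is deterministically ordered by (scaffold id, start).
    """
    selected = [
        a
        for a in assignments
        if a.status == "Assigned" and donor_filter(a.donor)
    ]

    def interval(a: GeneAssignment, ordinal: int) -> tuple[int, int]:
        if gene_intervals and a.gene_id in gene_intervals:
            start, end = gene_intervals[a.gene_id]
            scaffold_len = scaffold_lengths[a.scaffold_id]
            if not (1 <= start <= end <= scaffold_len):
                raise ValueError(
                    f"gene {a.gene_id} interval {start}-{end} outside scaffold "
                    f"{a.scaffold_id} (length {scaffold_len})"
                )
            return start, end
        return ordinal, ordinal

    keyed = sorted(
        ((a.scaffold_id, *interval(a, i + 1), a) for i, a in enumerate(selected)),
        key=lambda row: (row[0], row[1], row[3].gene_id),
    )
    scaffolds = sorted({row[0] for row in keyed})
    donor_slots: dict[str, int] = {}
    link_rows = []
    for scaffold_id, start, end, a in keyed:
        label = a.donor.subgroup or a.donor.superkingdom
        slot = donor_slots.get(label, 0) + 1
        donor_slots[label] = slot
        link_rows.append((scaffold_id, start, end, label, slot, a.gene_id))

    with open(karyotype_path, "w") as out:
        out.write("# chr - id label start end color\n")
        for scaffold_id in scaffolds:
            length = scaffold_lengths[scaffold_id]
            out.write(f"chr - {scaffold_id} {scaffold_id} 0 {length} grey\n")
        for label in sorted(donor_slots):
            out.write(
                f"chr - donor_{label} {label} 0 {donor_slots[label]} set2-{1 + sorted(donor_slots).index(label) % 8}\n"
            )
    with open(links_path, "w") as out:
        out.write("# scaffold start end donor slot_start slot_end gene_id\n")
        for scaffold_id, start, end, label, slot, gene_id in link_rows:
            out.write(
                f"{scaffold_id} {start} {end} donor_{label} {slot - 1} {slot} {gene_id}\n"
            )
    logger.info(
        "rhizome: %d links on %d scaffolds -> %s", len(link_rows), len(scaffolds), links_path
    )
    return len(link_rows), len(scaffolds)


def summary_report(
    donor_tally: DonorTally,
    assembly=None,
    length_filter: tuple[int, int] | None = None,
    intron_means: Mapping[str, float] | None = None,
    n_contaminant_genes: int | None = None,
    n_contaminant_scaffolds: int | None = None,
) -> dict:
    """Headline-number report: counts plus pct() shares at every level.

    ``length_filter`` is (n_passing, n_total) for the protein-length filter.
    """
    total = donor_tally.total_genes
    report: dict = {"total_genes": total, "orfan_genes": donor_tally.n_orfan}
    if total:
        report["orfan_pct"] = pct(donor_tally.n_orfan, total)
        report["superkingdom"] = {}
        for kingdom in ("Eukaryota", "Bacteria", "Archaea", "Viruses", "Unclassified"):
            count = donor_tally.by_superkingdom.get(kingdom, 0)
            report["superkingdom"][kingdom] = {"genes": count, "pct_of_total": pct(count, total)}
        amoebozoa = donor_tally.by_subgroup.get(("Eukaryota", "Amoebozoa"), 0)
        report["amoebozoa"] = {"genes": amoebozoa, "pct_of_total": pct(amoebozoa, total)}
        gv = donor_tally.giant_virus_total()
        report["giant_virus"] = {"genes": gv, "pct_of_total": pct(gv, total)}
    bacterial = donor_tally.total_bacterial
    if bacterial:
        report["bacterial_phyla"] = {
            subgroup: {"genes": count, "pct_of_bacterial": pct(count, bacterial)}
            for (kingdom, subgroup), count in sorted(
                donor_tally.by_subgroup.items(), key=lambda kv: -kv[1]
            )
            if kingdom == "Bacteria"
        }
        cpr = donor_tally.cpr_total()
        report["cpr"] = {"genes": cpr, "pct_of_bacterial": pct(cpr, bacterial)}
    if assembly is not None:
        report["assembly"] = {
            "total_bp": assembly.total_bp,
            "gc_pct": round(assembly.gc_pct, 1),
            "n_scaffolds": assembly.n_scaffolds,
            "max_len": assembly.max_len,
            "min_len": assembly.min_len,
            "n50": assembly.n50,
        }
    if length_filter is not None:
        passing, n_total = length_filter
        report["length_filter"] = {
            "genes_passing": passing,
            "pct_of_total": pct(passing, n_total) if n_total else None,
        }
    if intron_means is not None:
        report["mean_introns"] = {k: round(v, 1) for k, v in sorted(intron_means.items())}
    if n_contaminant_genes is not None:
        report["contamination"] = {
            "genes_removed": n_contaminant_genes,
            "scaffolds_excluded": n_contaminant_scaffolds,
        }
    return report


def write_summary(report: dict, json_path: str | Path, tsv_path: str | Path) -> None:
    with open(json_path, "w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
        out.write("\n")
    rows: list[tuple[str, str]] = []

    def flatten(prefix: str, value) -> None:
        if isinstance(value, dict):
            for key in value:
                flatten(f"{prefix}.{key}" if prefix else str(key), value[key])
        else:
            rows.append((prefix, "" if value is None else str(value)))

    flatten("", report)
    with open(tsv_path, "w") as out:
        out.write("metric\tvalue\n")
        for key, value in rows:
            out.write(f"{key}\t{value}\n")
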