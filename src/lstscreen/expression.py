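"""RNA-seq count attachment, transcription calls and candidate ranking.

Counts arrive as a two-column TSV (gene id, read count); rows whose id
starts with ``__`` are counter summary lines and are skipped.  A gene is
called transcribed when covered by at least ``min_reads`` reads (inclusive);
genes missing from the table count as zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

from .hits import GeneAssignment
from .taxonomy import DonorGroup

DEFAULT_MIN_READS = 5


def load_counts(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene_id, raw = fields
            if gene_id.startswith("__"):
                continue
            try:
                count = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count {raw!r}") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count for {gene_id}")
            if gene_id in counts:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            counts[gene_id] = count
    return counts


def write_counts(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as out:
        for gene_id in sorted(counts):
            out.write(f"{gene_id}\t{counts[gene_id]}\n")


def flag_transcribed(
    assignments: Sequence[GeneAssignment],
    counts: dict[str, int],
    min_reads: int = DEFAULT_MIN_READS,
) -> list[GeneAssignment]:
    """Return assignments with ``read_count`` and ``expressed`` populated."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [a.with_expression(counts.get(a.gene_id, 0), min_reads) for a in assignments]


def rank_expressed(
    assignments: Sequence[GeneAssignment],
    donor_filter: Callable[[DonorGroup], bool] | None = None,
    top_n: int | None = None,
) -> list[GeneAssignment]:
    """Expressed genes matching the donor predicate, by descending read count.

    Ties break by gene id so the ranking is permutation-invariant.  ORFans
    never match a donor predicate (they have no donor).
    """
    selected = []
    for a in assignments:
        if not a.expressed:
            continue
        if donor_filter is not None and (a.donor is None or not donor_filter(a.donor)):
            continue
        selected.append(a)
    selected.sort(key=lambda a: (-a.read_count, a.gene_id))
    return selected[:top_n] if top_n is not None else selected


def write_candidate_report(
    candidates: Sequence[GeneAssignment],
    path: str | Path,
    functions: dict[str, str] | None = None,
) -> None:
    """Candidate TSV: gene, donor subgroup, organism, function, read count."""
    with open(path, "w") as out:
        out.write("gene_id\tsubgroup\torganism\tfunction\tread_count\n")
        for a in candidates:
            function = (functions or {}).get(a.gene_id, "")
            subgroup = a.donor.subgroup if a.donor else ""
            out.write(
                f"{a.gene_id}\t{subgroup}\t{a.organism or ''}\t{function}\t{a.read_count}\n"
            )
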