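"""Taxonomy tree handling and donor-group classification.

A :class:`TaxonomyTree` is loaded from two tab-separated dump files
(nodes: ``taxid<TAB>parent<TAB>rank``; names: ``taxid<TAB>name``) and maps
any taxon id to its root-ward lineage.  :func:`classify` projects a taxon
onto the donor-group scheme used throughout the screen: a superkingdom plus
a subgroup label (Amoebozoa, a bacterial phylum, a CPR group, or a
giant-virus lineage), resolved by the most specific configured marker name
found on the lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Closed rank vocabulary accepted in node tables.
RANKS = frozenset(
    {"superkingdom", "phylum", "class", "order", "family", "genus", "species", "no_rank"}
)

SUPERKINGDOMS = ("Eukaryota", "Bacteria", "Archaea", "Viruses")

#: Hard cap on lineage depth; a longer parent walk indicates a corrupt table.
MAX_DEPTH = 64


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomy tables."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass(frozen=True)
class DonorGroup:
    """Donor label for one best hit: superkingdom plus subgroup.

    ``is_cpr`` and ``is_giant_virus`` are mutually exclusive; ``subgroup``
    is ``None`` only when the superkingdom is ``Unclassified``.
    """

    superkingdom: str
    subgroup: str | None
    is_cpr: bool = False
    is_giant_virus: bool = False

    def __post_init__(self) -> None:
        if self.is_cpr and self.superkingdom != "Bacteria":
            raise ValueError("is_cpr requires superkingdom Bacteria")
        if self.is_giant_virus and self.superkingdom != "Viruses":
            raise ValueError("is_giant_virus requires superkingdom Viruses")
        if self.is_cpr and self.is_giant_virus:
            raise ValueError("is_cpr and is_giant_virus are mutually exclusive")
        if self.subgroup is None and self.superkingdom != "Unclassified":
            raise ValueError("subgroup may be empty only for Unclassified")


UNCLASSIFIED = DonorGroup("Unclassified", None)


class TaxonomyTree:
    """Rooted taxon graph; the root is its own parent."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        root = None
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            if node.rank not in RANKS:
                raise TaxonomyError(f"unknown rank {node.rank!r} for taxid {node.taxid}")
            self.nodes[node.taxid] = node
            if node.parent_taxid == node.taxid:
                if root is not None:
                    raise TaxonomyError("multiple self-parented roots")
                root = node.taxid
        if root is None:
            raise TaxonomyError("missing root (no self-parented node)")
        self.root = root
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} has unknown parent {node.parent_taxid}"
                )
        # validate acyclicity / depth bound once, up front
        for taxid in self.nodes:
            self.lineage(taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, taxid: int) -> list[TaxonNode]:
        """Root-ward walk: starts at ``taxid``, ends at the root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        out = []
        current = taxid
        for _ in range(MAX_DEPTH + 1):
            node = self.nodes[current]
            out.append(node)
            if current == self.root:
                return out
            current = node.parent_taxid
        raise TaxonomyError(f"lineage of {taxid} exceeds {MAX_DEPTH} steps (cycle?)")

    def ancestor_at_rank(self, taxid: int, rank: str) -> TaxonNode | None:
        """Nearest lineage node of the given rank, or None."""
        for node in self.lineage(taxid):
            if node.rank == rank:
                return node
        return None

    def name_of(self, taxid: int) -> str | None:
        node = self.nodes.get(taxid)
        return node.name if node else None

    def find_by_name(self, name: str) -> TaxonNode | None:
        for node in self.nodes.values():
            if node.name == name:
                return node
        return None


def load_taxonomy(node_table: str | Path, name_table: str | Path) -> TaxonomyTree:
    """Load a tree from nodes (taxid, parent, rank) and names (taxid, name) TSVs."""
    names: dict[int, str] = {}
    with open(name_table) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TaxonomyError(f"{name_table}:{lineno}: expected 2 columns")
            names[int(fields[0])] = fields[1]
    nodes = []
    with open(node_table) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TaxonomyError(f"{node_table}:{lineno}: expected 3 columns")
            taxid = int(fields[0])
            nodes.append(
                TaxonNode(taxid, int(fields[1]), fields[2], names.get(taxid, str(taxid)))
            )
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, node_table: str | Path, name_table: str | Path) -> None:
    """Write a tree back to the two-table dump format (sorted by taxid)."""
    with open(node_table, "w") as nodes_out, open(name_table, "w") as names_out:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            nodes_out.write(f"{node.taxid}\t{node.parent_taxid}\t{node.rank}\n")
            names_out.write(f"{node.taxid}\t{node.name}\n")


@dataclass(frozen=True)
class GroupMarker:
    subgroup: str
    is_cpr: bool = False
    is_giant_virus: bool = False


class GroupConfig:
    """Mapping of lineage marker names to donor subgroup labels and flags.

    File format is a plain TSV: ``marker_name<TAB>subgroup<TAB>flags`` with
    flags in ``{cpr, giant_virus, -}``; '#' lines are comments.
    """

    def __init__(self, markers: Mapping[str, GroupMarker]):
        self.markers = dict(markers)

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupConfig":
        markers: dict[str, GroupMarker] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise TaxonomyError(f"{path}:{lineno}: expected 3 columns")
                name, subgroup, flags = fields
                if flags not in ("cpr", "giant_virus", "-"):
                    raise TaxonomyError(f"{path}:{lineno}: unknown flag {flags!r}")
                markers[name] = GroupMarker(
                    subgroup, is_cpr=flags == "cpr", is_giant_virus=flags == "giant_virus"
                )
        return cls(markers)

    @classmethod
    def default(cls) -> "GroupConfig":
        with resources.as_file(
            resources.files("lstscreen.data").joinpath("donor_groups.tsv")
        ) as path:
            return cls.from_file(path)


def classify(tree: TaxonomyTree, taxid: int, config: GroupConfig) -> DonorGroup:
    """Project a taxon onto the donor-group scheme.

    The superkingdom is the lineage's superkingdom-rank node; the subgroup is
    the most specific (query-nearest) configured marker on the lineage, with
    rank-based fallbacks (bacterial/archaeal phylum name, generic
    ``Other-...`` labels).  Unknown taxids classify as Unclassified with a
    warning rather than raising: hit tables routinely carry stale ids.
    """
    if taxid not in tree:
        logger.warning("taxid %s absent from taxonomy; classified as Unclassified", taxid)
        return UNCLASSIFIED
    lineage = tree.lineage(taxid)
    superkingdom = None
    for node in lineage:
        if node.rank == "superkingdom" and node.name in SUPERKINGDOMS:
            superkingdom = node.name
            break
    if superkingdom is None:
        return UNCLASSIFIED
    # most specific marker wins: lineage is ordered query -> root
    for node in lineage:
        marker = config.markers.get(node.name)
        if marker is None:
            continue
        if marker.is_cpr and superkingdom != "Bacteria":
            continue
        if marker.is_giant_virus and superkingdom != "Viruses":
            continue
        return DonorGroup(superkingdom, marker.subgroup, marker.is_cpr, marker.is_giant_virus)
    if superkingdom in ("Bacteria", "Archaea"):
        phylum = next((n for n in lineage if n.rank == "phylum"), None)
        if phylum is not None:
            return DonorGroup(superkingdom, phylum.name)
    fallback = {
        "Eukaryota": "Other-eukaryote",
        "Bacteria": "Other-bacteria",
        "Archaea": "Other-archaea",
        "Viruses": "Other-virus",
    }
    return DonorGroup(superkingdom, fallback[superkingdom])
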