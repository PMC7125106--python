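"""Tree-based support for candidate transfers.

p-distances from a protein alignment (pairwise gap deletion), classical
neighbor joining with deterministic tie-breaking, bootstrap supports by
column resampling, and a donor-congruence test: after midpoint rooting,
a transfer is "supported" when the query leaf's sister clade contains at
least one putative-donor leaf and no outgroup leaf.

Neighbor joining is implemented here rather than delegated: the screen's
tests rely on its exact tie-breaking (smallest index pair in the Q matrix)
and on negative-branch clamping with the excess moved to the sibling edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = ord("-")


class AlignmentError(ValueError):
    pass


class ProteinAlignment:
    """Equal-length aligned protein sequences, >= 3 rows, gap symbol '-'."""

    def __init__(self, ids: Sequence[str], seqs: Sequence[str]):
        if len(ids) != len(seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(ids) < 3:
            raise AlignmentError("alignment needs >= 3 sequences")
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentError("zero-column alignment")
        self.ids = list(ids)
        self.matrix = np.array(
            [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
        )

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, idx: int) -> str:
        return self.matrix[idx].tobytes().decode("ascii")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for i, seq_id in enumerate(self.ids):
                out.write(f">{seq_id}\n{self.sequence(i)}\n")

    def resample_columns(self, indices: np.ndarray) -> "ProteinAlignment":
        new = object.__new__(ProteinAlignment)
        new.ids = list(self.ids)
        new.matrix = self.matrix[:, indices]
        return new

    def reorder(self, ids: Sequence[str]) -> "ProteinAlignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        new = object.__new__(ProteinAlignment)
        new.ids = list(ids)
        new.matrix = self.matrix[[index[sid] for sid in ids], :]
        return new


class DistanceMatrix:
    """Square symmetric non-negative matrix with zero diagonal."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = len(ids)
        if matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(matrix < 0):
            raise ValueError("distances must be non-negative")
        self.ids = list(ids)
        self.matrix = matrix

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.matrix[i, j])


def p_distance(alignment: ProteinAlignment) -> DistanceMatrix:
    """Mismatch fraction over columns where neither sequence has a gap.

    A pair with zero comparable columns gets distance 1.0 with a warning.
    """
    m = alignment.matrix
    n = m.shape[0]
    out = np.zeros((n, n))
    gapped = m == GAP
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gapped[i] | gapped[j])
            n_comp = int(comparable.sum())
            if n_comp == 0:
                logger.warning(
                    "no comparable columns between %s and %s; distance set to 1.0",
                    alignment.ids[i],
                    alignment.ids[j],
                )
                d = 1.0
            else:
                d = float(((m[i] != m[j]) & comparable).sum()) / n_comp
            out[i, j] = out[j, i] = d
    return DistanceMatrix(alignment.ids, out)


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the NJ result is rooted at a trident."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset({self.name})
        return frozenset().union(*(c.leaf_names() for c, _ in self.children))


@dataclass
class SupportTree:
    """Unrooted tree with optional bootstrap supports on internal edges."""

    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{length:.10g}" for c, length in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions, keyed canonically (the side not
        containing the lexicographically smallest leaf)."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = child.leaf_names()
                    if ref in side:
                        side = all_leaves - side
                    # keep non-trivial splits only (>= 2 leaves on each side)
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        out[frozenset(side)] = child
                    walk(child)

        walk(self.root)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""

        def find(node: TreeNode, target: str):
            """Leaf-to-node path as (nodes, edge_lengths); lengths[k] joins
            nodes[k] to nodes[k+1]."""
            if node.is_leaf:
                return ([node], []) if node.name == target else None
            for child, length in node.children:
                found = find(child, target)
                if found is not None:
                    nodes, lengths = found
                    return nodes + [node], lengths + [length]
            return None

        found_a = find(self.root, a)
        found_b = find(self.root, b)
        if found_a is None or found_b is None:
            raise KeyError("unknown leaf id")
        nodes_a, lengths_a = found_a
        nodes_b, lengths_b = found_b
        pos_b = {id(node): k for k, node in enumerate(nodes_b)}
        dist_a = 0.0
        for k, node in enumerate(nodes_a):
            if id(node) in pos_b:
                return dist_a + sum(lengths_b[: pos_b[id(node)]])
            dist_a += lengths_a[k]
        raise RuntimeError("leaf paths do not meet at the root")


def neighbor_joining(dist: DistanceMatrix) -> SupportTree:
    """Classical NJ with deterministic tie-breaking.

    The Q-matrix minimum is resolved toward the smallest (i, j) index pair;
    a negative branch length is clamped to zero with the excess moved to the
    sibling edge, so path lengths across the joined pair are preserved.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]
    d = dist.matrix.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # argmin over the upper triangle in row-major order: the first
        # minimum is the smallest (i, j) pair, which is the tie-break rule
        upper = np.triu_indices(m, k=1)
        k = int(np.argmin(q[upper]))
        i, j = int(upper[0][k]), int(upper[1][k])
        dij = d[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        new_node = TreeNode(children=[(nodes[i], float(bi)), (nodes[j], float(bj))])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = new_row[keep]
        d_next[:-1, -1] = new_row[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [new_node]

    dxy, dxz, dyz = d[0, 1], d[0, 2], d[1, 2]
    lx = max(0.0, 0.5 * (dxy + dxz - dyz))
    ly = max(0.0, 0.5 * (dxy + dyz - dxz))
    lz = max(0.0, 0.5 * (dxz + dyz - dxy))
    root = TreeNode(
        children=[(nodes[0], float(lx)), (nodes[1], float(ly)), (nodes[2], float(lz))]
    )
    return SupportTree(root)


def bootstrap_support(
    alignment: ProteinAlignment, n_reps: int = 100, seed: int = 0
) -> SupportTree:
    """NJ point estimate annotated with column-resampling bootstrap supports.

    The alignment rows are canonically ordered (sorted ids) before tree
    building, so supports are invariant to the input leaf order; the seed
    fixes the column-resampling stream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    canonical = alignment.reorder(sorted(alignment.ids))
    point = neighbor_joining(p_distance(canonical))
    point_bips = point.bipartitions()
    counts = {bip: 0 for bip in point_bips}
    rng = np.random.default_rng(seed)
    n_cols = canonical.n_columns
    for _ in range(n_reps):
        indices = rng.integers(0, n_cols, size=n_cols)
        replicate = neighbor_joining(p_distance(canonical.resample_columns(indices)))
        replicate_bips = replicate.bipartitions()
        for bip in counts:
            if bip in replicate_bips:
                counts[bip] += 1
    for bip, node in point_bips.items():
        node.support = 100.0 * counts[bip] / n_reps
    return point


@dataclass(frozen=True)
class CongruenceResult:
    verdict: str  # "supported" | "unsupported"
    sister_leaves: tuple[str, ...]
    support: float | None

    @property
    def supported(self) -> bool:
        return self.verdict == "supported"


def congruence_test(
    tree: SupportTree,
    query_leaf: str,
    donor_leaves: Iterable[str],
    outgroup_leaves: Iterable[str],
) -> CongruenceResult:
    """Midpoint-root the tree and inspect the query's sister clade.

    Supported iff the sister clade contains >= 1 donor leaf and 0 outgroup
    leaves.  Midpoint rooting makes the verdict invariant to how the input
    tree happens to be rooted.
    """
    donors = set(donor_leaves)
    outgroups = set(outgroup_leaves)
    leaves = tree.leaf_names()
    for label, group in (("query", {query_leaf}), ("donor", donors), ("outgroup", outgroups)):
        missing = group - leaves
        if missing:
            raise KeyError(f"unknown {label} leaf id(s): {sorted(missing)}")
    if {query_leaf} & donors or {query_leaf} & outgroups or donors & outgroups:
        raise ValueError("query, donor and outgroup leaf sets must be disjoint")

    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    dtree.reroot_at_midpoint(update_bipartitions=False)
    node = next(
        (leaf for leaf in dtree.leaf_node_iter() if leaf.taxon.label == query_leaf), None
    )
    if node is None:
        raise KeyError(f"unknown leaf id {query_leaf}")
    parent = node.parent_node
    # climb past degree-2 artifacts (possible at the midpoint root)
    while parent is not None and len(parent.child_nodes()) < 2:
        parent = parent.parent_node
    if parent is None:
        raise ValueError("query leaf has no sister clade (degenerate tree)")
    sister = tuple(
        sorted(
            leaf.taxon.label
            for child in parent.child_nodes()
            if child is not node
            for leaf in child.leaf_iter()
        )
    )
    support = None
    if parent.label is not None:
        try:
            support = float(parent.label)
        except ValueError:
            support = None
    sister_set = set(sister)
    supported = bool(sister_set & donors) and not (sister_set & outgroups)
    return CongruenceResult(
        "supported" if supported else "unsupported", sister, support
    )


def write_congruence_report(
    results: dict[str, CongruenceResult], path: str | Path
) -> None:
    """Verdict TSV: one row per tested candidate gene."""
    with open(path, "w") as out:
        out.write("gene_id\tverdict\tsupport\tsister_leaves\n")
        for gene_id in sorted(results):
            res = results[gene_id]
            support = "" if res.support is None else f"{res.support:g}"
            out.write(f"{gene_id}\t{res.verdict}\t{support}\t{','.join(res.sister_leaves)}\n")
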