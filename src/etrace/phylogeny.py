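"""Neighbor-joining tree construction and two-group partition of its leaves.

The tree input is an uncorrected p-distance matrix computed from the
alignment (mismatch fraction over columns where neither row is a gap).
Trees are held as :class:`skbio.TreeNode` objects; the unrooted NJ topology
is represented with a degree-3 root.  A partition cut removes one edge and
labels the two resulting leaf sets as groups 1 and 2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .alignio import GAP, MultipleAlignment


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distances

def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances: mismatches / comparable (gap-free) columns."""
    if len(msa.records) < 3:
        raise PhylogenyError("need at least 3 records for a distance matrix")
    n = len(msa.records)
    d = np.zeros((n, n))
    seqs = [r.residues for r in msa.records]
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x != GAP and y != GAP:
                    comparable += 1
                    if x != y:
                        mismatch += 1
            if comparable == 0:
                raise PhylogenyError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(d, ids=msa.ids)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties are broken by the lexicographically smallest pair of
    subtree labels (each active node is keyed by the smallest leaf label it
    contains).  Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch, preserving the joined pair's path
    length.
    """
    if isinstance(dm, np.ndarray):
        raise TypeError("pass a skbio DistanceMatrix with ids")
    n = len(dm.ids)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    if np.any(dm.data < 0):
        raise PhylogenyError("negative distances in input")

    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=str(label)) for label in dm.ids]
    keys = [str(label) for label in dm.ids]  # smallest leaf label per subtree
    active = list(range(n))

    def split_lengths(dij: float, li: float) -> tuple[float, float]:
        lj = dij - li
        if li < 0:
            return 0.0, dij
        if lj < 0:
            return dij, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        li, lj = split_lengths(dij, li)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = np.array([0.5 * (d[i, k] + d[j, k] - dij) for k in range(d.shape[0])])
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        d[d < 0] = 0.0
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, length in ((nodes[i], la), (nodes[j], lb), (nodes[k], lc)):
        node.length = max(length, 0.0)
    order = sorted((i, j, k), key=lambda idx: keys[idx])
    return TreeNode(children=[nodes[idx] for idx in order])


# ---------------------------------------------------------------------------
# Newick I/O

def write_newick(tree: TreeNode, path=None) -> str:
    """Serialise with 10 significant digits on branch lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    text = fmt(tree) + ";\n"
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and source.rstrip().endswith(";"):
        return TreeNode.read(io.StringIO(source), format="newick", convert_underscores=False)
    return TreeNode.read(str(source), format="newick", convert_underscores=False)


# ---------------------------------------------------------------------------
# Partitions

@dataclass
class GroupPartition:
    """Disjoint cover of tree leaves into numbered groups (1..k)."""

    assignment: dict[str, int]
    cut_edge: str | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise PhylogenyError("empty partition")
        groups = set(self.assignment.values())
        if groups != set(range(1, len(groups) + 1)):
            raise PhylogenyError("group ids must be 1..k")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def group(self, gid: int) -> list[str]:
        return sorted(l for l, g in self.assignment.items() if g == gid)

    def group_of(self, label: str) -> int:
        return self.assignment[label]

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("leaf_id\tgroup\n")
            for label in sorted(self.assignment):
                fh.write(f"{label}\t{self.assignment[label]}\n")

    @classmethod
    def from_tsv(cls, path) -> "GroupPartition":
        assignment = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("leaf_id"):
                raise PhylogenyError("partition TSV must have a leaf_id/group header")
            for line in fh:
                if line.strip():
                    label, gid = line.split("\t")
                    assignment[label.strip()] = int(gid)
        return cls(assignment)


def _canonical_edges(tree: TreeNode) -> list[tuple[str, TreeNode]]:
    """Deterministic edge enumeration: each non-root node is one edge to its
    parent, listed in preorder with children visited by smallest contained
    leaf label.  Stable across Newick round-trips."""
    min_leaf: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_tip():
            min_leaf[id(node)] = node.name
        else:
            min_leaf[id(node)] = min(min_leaf[id(c)] for c in node.children)
    edges: list[tuple[str, TreeNode]] = []

    def visit(node: TreeNode) -> None:
        for child in sorted(node.children, key=lambda c: min_leaf[id(c)]):
            edges.append((f"E{len(edges)}", child))
            visit(child)

    visit(tree)
    return edges


def edge_ids(tree: TreeNode) -> dict[str, list[str]]:
    """Map each edge id to the sorted leaf labels below it (for display)."""
    return {
        eid: sorted(t.name for t in (node.tips() if not node.is_tip() else [node]))
        for eid, node in _canonical_edges(tree)
    }


def _resolve_edge(tree: TreeNode, edge: str) -> tuple[str, TreeNode]:
    edges = _canonical_edges(tree)
    for eid, node in edges:
        if eid == edge or (node.is_tip() and node.name == edge):
            return eid, node
    raise PhylogenyError(
        f"unknown edge {edge!r}; valid ids are E0..E{len(edges) - 1} or leaf labels"
    )


def partition_at_edge(tree: TreeNode, edge: str) -> GroupPartition:
    """Cut one edge; the two connected leaf sets become groups 1 and 2.

    Group 1 is the side containing the lexicographically smallest leaf.
    """
    eid, node = _resolve_edge(tree, edge)
    below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
    all_leaves = {t.name for t in tree.tips()}
    above = all_leaves - below
    if not above:
        raise PhylogenyError(f"edge {edge!r} does not split the leaf set")
    if min(below) < min(above):
        sides = (below, above)
    else:
        sides = (above, below)
    assignment = {label: 1 for label in sides[0]}
    assignment.update({label: 2 for label in sides[1]})
    return GroupPartition(assignment, cut_edge=eid)


def auto_partition(tree: TreeNode, k: int = 2) -> GroupPartition:
    """Pick the deepest split: the edge maximising the minimum inter-group
    leaf-to-leaf path length; ties broken by the most balanced split, then
    by canonical edge order."""
    if k != 2:
        raise PhylogenyError("unsupported: only two-group partitions are implemented")
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 2:
        raise PhylogenyError("need at least 2 leaves")

    down: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            down[id(node)] = 0.0
        else:
            down[id(node)] = min(
                down[id(c)] + (c.length or 0.0) for c in node.children
            )
    out: dict[int, float] = {}
    for node in tree.preorder():
        for child in node.children:
            options = [
                down[id(s)] + (s.length or 0.0) for s in node.children if s is not child
            ]
            if node.parent is not None:
                options.append(out[id(node)] + (node.length or 0.0))
            out[id(child)] = min(options)

    n_total = len(leaves)
    best = None
    for idx, (eid, node) in enumerate(_canonical_edges(tree)):
        n_below = sum(1 for _ in node.tips()) if not node.is_tip() else 1
        if n_below == 0 or n_below == n_total:
            continue
        depth = down[id(node)] + (node.length or 0.0) + out[id(node)]
        key = (-depth, abs(n_total - 2 * n_below), idx)
        if best is None or key < best[0]:
            best = (key, eid)
    return partition_at_edge(tree, best[1])
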