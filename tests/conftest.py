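"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import etrace as et


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never call package internals)

def brute_force_global_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Exhaustive enumeration of all global alignments (len <= 8)."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + rec(i + 1, j + 1))
        if i < len(a):
            options.append(gap + rec(i + 1, j))
        if j < len(b):
            options.append(gap + rec(i, j + 1))
        return max(options)

    return rec(0, 0)


def brute_force_site(structure: et.Structure, ligand_coords: np.ndarray, cutoff: float):
    """All-pairs python-loop contact scan; returns sorted residue numbers."""
    found = []
    for chain in structure.chains:
        for res in chain.residues:
            if res.is_water or res.het:
                continue
            dmin = min(
                float(np.linalg.norm(np.array([a.x, a.y, a.z]) - l))
                for a in res.atoms
                for l in ligand_coords
            )
            if dmin <= cutoff:
                found.append(res.seqnum)
    return sorted(found)


def tree_bipartitions(tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller-side frozensets won't be
    unique, store the side below each internal edge)."""
    all_leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips():
        if node.parent is None:
            continue
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_leaves) - 1:
            parts.add(min(below, all_leaves - below, key=sorted))
    return parts


def leaf_path_lengths(tree) -> dict[tuple[str, str], float]:
    """Pairwise leaf-to-leaf path lengths via lowest common ancestors."""
    tips = list(tree.tips())
    depth = {}
    for tip in tips:
        d, node = 0.0, tip
        chain = []
        while node is not None:
            chain.append((node, d))
            d += node.length or 0.0
            node = node.parent
        depth[tip.name] = dict((id(n), dd) for n, dd in chain)
        depth[tip.name + "/chain"] = chain
    out = {}
    for i, ta in enumerate(tips):
        for tb in tips[i + 1 :]:
            da = depth[ta.name]
            for node, db in depth[tb.name + "/chain"]:
                if id(node) in da:
                    out[tuple(sorted((ta.name, tb.name)))] = da[id(node)] + db
                    break
    return out


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree with positive branch lengths and its leaf
    distance matrix (additive by construction)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[b, a])
        parent.length = float(rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    dists = leaf_path_lengths(root)
    labels = sorted(f"t{i}" for i in range(n_leaves))
    d = np.zeros((n_leaves, n_leaves))
    for ai, la in enumerate(labels):
        for bi in range(ai + 1, n_leaves):
            d[ai, bi] = d[bi, ai] = dists[(la, labels[bi])]
    return root, labels, d


# ---------------------------------------------------------------------------
# Fixtures

@pytest.fixture
def small_family():
    """Deterministic planted family used by several modules."""
    return et.simulate_family(et.FamilySpec(length=60, seqs_per_group=4, seed=11))


@pytest.fixture
def toy_complex():
    spec = et.ToyComplexSpec(
        n_residues=20,
        geometry="straight",
        ligand_placements=((5, 4.9, (0.0, 0.0, 1.0)),),
        seed=3,
    )
    return et.simulate_complex(spec)
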