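"""Alignment-free distances and neighbor-joining trees over OTU representatives.

OTU representatives are mixed-length (stitched paired segments next to
forward-only reads), so distances are computed from shared k-mer sets —
insensitive to end gaps and to the N spacer by construction — and a
deterministic neighbor-joining tree is built for UniFrac. This is a
deliberate, documented stand-in for structural alignment + approximate-ML
tree building; an externally built Newick tree can be supplied instead
anywhere a tree is consumed.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .taxonomy import extract_words


def kmer_distance_matrix(seqs: dict[str, str], k: int = 6) -> DistanceMatrix:
    """d(a,b) = 1 - |Ka ∩ Kb| / min(|Ka|, |Kb|) over k-mer sets.

    k-mers containing N are skipped, so stitched spacers contribute
    nothing. A sequence with no valid k-mer of length >= k is a hard error
    naming the OTU.
    """
    ids = list(seqs)
    sets: list[set[int]] = []
    for otu_id in ids:
        if len(seqs[otu_id]) < k:
            raise ValueError(f"sequence for {otu_id!r} shorter than k={k}")
        kmers = set(extract_words(seqs[otu_id].upper(), k).tolist())
        if not kmers:
            raise ValueError(f"sequence for {otu_id!r} has no N-free {k}-mers")
        sets.append(kmers)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            D[i, j] = D[j, i] = 1.0 - shared / min(len(sets[i]), len(sets[j]))
    return DistanceMatrix(D, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaking.

    Saitou–Nei Q-criterion and standard branch-length formulas; ties on Q
    are broken by label order. A negative pendant length is clipped to 0
    with the deficit moved to its sibling (total preserved), so additive
    matrices are still recovered exactly. Two taxa yield a single edge
    split evenly; the final join leaves a trifurcating (unrooted-style)
    root for >= 3 taxa.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("neighbor_joining needs at least 2 labels")
    D = np.array(dm.data, dtype=float)
    if (D < 0).any():
        raise ValueError("negative distances")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    labels = list(ids)  # current label used for deterministic tie-breaks

    while len(nodes) > 3:
        n = len(nodes)
        R = D.sum(axis=1)
        best = None  # (Q, label_i, label_j, i, j)
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - R[i] - R[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[x] for x in keep] + [new]
        labels = [labels[x] for x in keep] + [new_label]

    if len(nodes) == 2:
        half = 0.5 * D[0, 1]
        nodes[0].length = half
        nodes[1].length = half
        return TreeNode(children=nodes)
    # three nodes: closed-form star lengths
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
    return TreeNode(children=nodes)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-root a copy of the tree (identity for a 2-child root)."""
    t = tree.copy()
    if len(t.children) == 2:
        return t
    return t.root_at_midpoint()


def _newick(node: TreeNode) -> str:
    if node.is_tip():
        return f"{node.name}:{(node.length or 0.0):.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    if node.length is None:
        return f"({inner})"
    return f"({inner}):{node.length:.6f}"


def write_newick(tree: TreeNode, path: str | None = None) -> str:
    """Serialize with branch lengths at 6 decimal places; optionally to file."""
    tips = [t.name for t in tree.tips()] or [tree.name]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate leaf labels")
    if tree.is_tip():
        s = f"({tree.name}:{(tree.length or 0.0):.6f});"
    else:
        s = _newick(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def read_newick(path: str) -> TreeNode:
    # keep literal underscores in OTU ids
    return TreeNode.read(path, format="newick", convert_underscores=False)
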