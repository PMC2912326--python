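"""Neighbor-joining tree construction (Saitou–Nei with the
Studier–Keppler criterion) and Newick serialisation.

Ties in the minimum-Q search are broken by lexicographic order of the
joined node labels, making the topology a pure function of the input
matrix.  Negative branch lengths are clamped to zero (the original value
is logged) unless clamping is disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

_NEWICK_RESERVED = set("();:, \t'\"[]")


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    label: str
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a root trifurcation."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distance matrix."""
        # distances from every node to each leaf via post-order traversal
        leaves = self.root.leaves()
        labels = [l.label for l in leaves]
        index = {id(l): i for i, l in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[id(node)]: 0.0}
            below: list[dict[int, float]] = []
            for child in node.children:
                d = walk(child)
                below.append({k: v + child.length for k, v in d.items()})
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for i, di in below[a].items():
                        for j, dj in below[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            merged: dict[int, float] = {}
            for d in below:
                merged.update(d)
            return merged

        walk(self.root)
        return labels, dist


def neighbor_joining(dist: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Canonical NJ: repeatedly join the pair minimising
    Q(i,j) = (N-2) d(i,j) - r_i - r_j, with limb lengths
    l_i = d(i,j)/2 + (r_i - r_j)/(2(N-2)); consistent (exact) on additive
    matrices."""
    n = dist.n
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    d = np.asarray(dist.values, dtype=float).copy()
    if np.isnan(d).any():
        raise TreeError("distance matrix contains NaN")
    nodes: list[TreeNode] = [TreeNode(str(s)) for s in dist.sample_ids]
    # sort keys: lexicographic labels for deterministic tie-breaks
    labels: list[str] = [node.label for node in nodes]

    def clamp(x: float) -> float:
        if clamp_negative and x < 0:
            logger.info("negative branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] / 2 + (r[j] - r[i]) / (2 * (m - 2)))
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(f"({labels[i]},{labels[j]})", children=[nodes[i], nodes[j]])
        # distances from the new node to the others
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dn[keep]
        d_new[:-1, -1] = dn[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[x] for x in keep] + [new]
        labels = [labels[x] for x in keep] + [new.label]

    # terminal 3-taxon star: closed-form limb lengths
    a, b, c = nodes
    a.length = clamp((d[0, 1] + d[0, 2] - d[1, 2]) / 2)
    b.length = clamp((d[0, 1] + d[1, 2] - d[0, 2]) / 2)
    c.length = clamp((d[0, 2] + d[1, 2] - d[0, 1]) / 2)
    return PhyloTree(root=TreeNode("", children=[a, b, c]))


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Newick text with branch lengths; child order is insertion order and
    reserved characters in labels are single-quoted."""

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            body = _quote(node.label)
        else:
            body = "(" + ",".join(render(c, True) for c in node.children) + ")"
        if with_length:
            body += f":{node.length:.{precision}g}"
        return body

    return render(tree.root, False) + ";"


def population_clades_monophyletic(tree: PhyloTree, pop_of: dict[str, str]) -> bool:
    """True when every population's leaves form a clade under some rooting,
    i.e. each population is contiguous on the unrooted tree.

    Checked via splits: a population is monophyletic on an unrooted tree
    iff some edge-split separates exactly that leaf set.
    """
    leaves = set(pop_of)
    splits: list[set[str]] = []

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            s = {node.label}
        else:
            s = set()
            for c in node.children:
                s |= walk(c)
        splits.append(s)
        return s

    walk(tree.root)
    pops = set(pop_of.values())
    for pop in pops:
        members = {leaf for leaf, p in pop_of.items() if p == pop}
        if len(members) <= 1:
            continue
        if not any(s == members or (leaves - s) == members for s in splits):
            return False
    return True
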