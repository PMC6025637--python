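"""Neighbor-joining trees with bootstrap support.

Topology search is deliberately out of scope for this package: family
clusters are validated on distance-based neighbor joining, which is exact on
additive matrices.  The implementation is the canonical Saitou-Nei /
Studier-Keppler algorithm with two fixed conventions: ties in the Q
criterion are broken by the lowest (i, j) index pair, and negative branch
lengths are clamped to zero (counted on the tree, never silent).

Bootstrap supports are percentages of column-resampled replicate NJ trees
containing each bipartition of the point-estimate tree; all resampling flows
through an explicit seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import MultipleAlignment, strip_gap_columns
from .distance import DistanceMatrix, distance_matrix
from .errors import DistanceError
from .substitution import SubstitutionModel

__all__ = ["TreeNode", "PhyloTree", "nj_tree", "bootstrap_support"]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # edge above this node
    support: float | None = None
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
    """Unrooted tree held with a trifurcating root."""

    root: TreeNode
    clamped_branches: int = 0

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits, keyed by the leaf-set side not containing the
        lexicographically smallest leaf (canonical for an unrooted tree)."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out[frozenset(side)] = node
            return below

        walk(self.root)
        return out

    def to_newick(self, support_labels: bool = True) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.8f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if support_labels and node.support is not None:
                label = f"{node.support:g}"
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.8f}"

        return fmt(self.root, top=True) + ";"


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining; exact on additive matrices.

    Deterministic: the joined pair is the Q-minimal pair with the lowest
    (i, j) indices in current join order.  Negative branch lengths are
    clamped to zero and counted in ``clamped_branches``.
    """
    n = len(matrix.ids)
    if n < 3:
        raise DistanceError("neighbor joining needs at least three taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise DistanceError("non-finite distances")
    d = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_idx = len(nodes)
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three-way join: closed-form three-point formulas
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, l in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = clamp(l)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, clamped_branches=clamped)


def bootstrap_support(
    msa: MultipleAlignment,
    model: SubstitutionModel,
    replicates: int = 200,
    seed: int | np.random.Generator = 0,
    gap_policy: str = "complete",
) -> PhyloTree:
    """Point-estimate NJ tree annotated with bootstrap percentages.

    Columns of the (complete-deletion) alignment are resampled with
    replacement; each replicate gets its own distance matrix and NJ tree,
    and every bipartition of the point tree is scored by the percentage of
    replicates containing it.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    work = strip_gap_columns(msa) if gap_policy == "complete" else msa
    point = nj_tree(distance_matrix(work, model, gap_policy="pairwise"))
    splits = point.bipartitions()
    hits = {s: 0 for s in splits}
    ncol = work.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = MultipleAlignment(
            ids=list(work.ids),
            rows=["".join(r[c] for c in cols) for r in work.rows],
            reference_id=work.reference_id,
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep, model, gap_policy="pairwise"))
        except DistanceError:
            continue
        rep_splits = set(rep_tree.bipartitions())
        for s in hits:
            if s in rep_splits:
                hits[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * hits[s] / replicates
    return point
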