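"""Neighbor joining: exactness on additive matrices, oracles, bootstrap."""

from itertools import combinations

import dendropy
import numpy as np
import pytest

from actinofam.align import MultipleAlignment
from actinofam.distance import DistanceMatrix, distance_matrix
from actinofam.errors import DistanceError
from actinofam.tree import bootstrap_support, nj_tree


def additive_matrix_from_tree(newick, taxa):
    """Path-length matrix of a Newick tree (dendropy does the path sums)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tns}
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(ids=list(taxa), values=d)


def splits_of(tree):
    return set(tree.bipartitions().keys())


def enumerate_topologies(taxa):
    """All unrooted binary topologies over ``taxa``, as non-trivial split sets.

    Stepwise addition: every topology on n taxa arises exactly once by
    attaching the n-th taxon to one of the 2n-5 edges of a topology on n-1
    taxa.  Trees are held as edge lists over leaf names and internal ids.
    """
    n = len(taxa)
    if n < 4:
        return [set()]

    def splits(edges):
        # adjacency; cutting each edge yields the leaf set of one side
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def side(u, v):
            # leaves reachable from v without crossing u
            stack, seen, leaves = [v], {u, v}, []
            while stack:
                x = stack.pop()
                if isinstance(x, str):
                    leaves.append(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            return leaves

        anchor = taxa[0]
        out = set()
        for u, v in edges:
            leaves = side(u, v)
            if 2 <= len(leaves) <= n - 2:
                s = set(leaves)
                out.add(frozenset(s if anchor not in s else set(taxa) - s))
        return out

    trees = [[(0, taxa[0]), (0, taxa[1]), (0, taxa[2])]]
    next_internal = 1
    for leaf in taxa[3:]:
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal
                grown.append(
                    edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (w, leaf)]
                )
        next_internal += 1
        trees = grown
    return [splits(e) for e in trees]


def least_squares_fit(splits, taxa, dmat):
    """OLS branch-length fit of a topology; returns residual sum of squares."""
    n = len(taxa)
    pairs = list(combinations(range(n), 2))
    # edges: pendant edge per taxon + internal edge per split
    edges = [frozenset([t]) for t in taxa] + [frozenset(s) for s in splits]
    design = np.zeros((len(pairs), len(edges)))
    for r, (i, j) in enumerate(pairs):
        for c, e in enumerate(edges):
            # edge separates i from j iff exactly one of them is in the leaf set
            design[r, c] = (taxa[i] in e) != (taxa[j] in e)
    y = np.array([dmat.values[i, j] for i, j in pairs])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((design @ coef - y) ** 2))


class TestNjExactness:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            ids=["a", "b", "c"],
            values=np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
        )
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_recovery(self):
        newick = "((A:0.1,B:0.2):0.05,C:0.3,D:0.4);"
        dmat = additive_matrix_from_tree(newick, ["A", "B", "C", "D"])
        tree = nj_tree(dmat)
        assert splits_of(tree) == {frozenset({"C", "D"})} or splits_of(tree) == {
            frozenset({"A", "B"})
        }
        # branch lengths: total tree length is preserved exactly
        total = sum(n.length for n in _all_nodes(tree.root))
        assert total == pytest.approx(0.1 + 0.2 + 0.05 + 0.3 + 0.4, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [5, 6])
    def test_additive_recovery_matches_least_squares_oracle(self, seed, n):
        """On additive matrices NJ must find the (unique) zero-residual
        topology that exhaustive least-squares enumeration finds."""
        taxa = [f"t{i}" for i in range(n)]
        newick = _random_tree_newick(taxa, seed)
        dmat = additive_matrix_from_tree(newick, taxa)
        tree = nj_tree(dmat)
        topos = enumerate_topologies(taxa)
        rss = [least_squares_fit(t, taxa, dmat) for t in topos]
        best = topos[int(np.argmin(rss))]
        assert min(rss) < 1e-18
        assert splits_of(tree) == {frozenset(s) for s in best}

    def test_agrees_with_dendropy_nj(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(7)]
        newick = _random_tree_newick(taxa, 11)
        dmat = additive_matrix_from_tree(newick, taxa)
        # perturb slightly so the matrix is only near-additive
        noise = rng.normal(0, 1e-4, dmat.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dmat2 = DistanceMatrix(ids=taxa, values=np.abs(dmat.values + noise))
        mine = nj_tree(dmat2)
        tns = dendropy.TaxonNamespace(taxa)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_csv_of(dmat2), taxon_namespace=tns, delimiter=","
        )
        ref = pdm.nj_tree()
        ref_splits = set()
        anchor = min(taxa)
        for edge in ref.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
                below = {l.taxon.label for l in edge.head_node.leaf_iter()}
                if 2 <= len(below) <= len(taxa) - 2:
                    side = below if anchor not in below else set(taxa) - below
                    ref_splits.add(frozenset(side))
        assert splits_of(mine) == ref_splits

    def test_negative_branches_clamped_and_counted(self):
        # deliberately non-additive matrix that forces a negative NJ branch
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.02],
                [0.4, 0.4, 0.02, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(ids=list("abcd"), values=d))
        assert all(n.length >= 0 for n in _all_nodes(tree.root))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(DistanceError):
            nj_tree(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))

    def test_non_finite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(DistanceError):
            nj_tree(DistanceMatrix(ids=list("abc"), values=d))


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self):
        taxa = [f"t{i}" for i in range(6)]
        dmat = additive_matrix_from_tree(_random_tree_newick(taxa, 2), taxa)
        tree = nj_tree(dmat)
        reread = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in reread.leaf_node_iter()} == set(taxa)
        total_mine = sum(n.length for n in _all_nodes(tree.root))
        total_reread = sum(
            e.length or 0.0 for e in reread.preorder_edge_iter()
        )
        assert total_reread == pytest.approx(total_mine, abs=1e-6)


class TestBootstrap:
    def _family_msa(self, small_family):
        _, proteins, _, truth = small_family
        matures = {k: v[34:] for k, v in proteins.items()}
        return MultipleAlignment(
            ids=truth.leaf_labels, rows=[matures[l] for l in truth.leaf_labels]
        )

    def test_supports_bounded(self, small_family, model):
        msa = self._family_msa(small_family)
        tree = bootstrap_support(msa, model, replicates=20, seed=1)
        sups = [n.support for n in _all_nodes(tree.root) if n.support is not None]
        assert sups and all(0.0 <= s <= 100.0 for s in sups)

    def test_uniform_partition_columns_give_full_support(self, model):
        # every column splits taxa the same way -> that bipartition is in
        # every replicate tree
        cols = ["AAWW", "SSGG", "KKEE", "LLVV"] * 10
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        tree = bootstrap_support(msa, model, replicates=25, seed=3)
        (node,) = [n for n in _all_nodes(tree.root) if n.support is not None]
        assert node.support == 100.0

    def test_reproducible_bit_exactly(self, small_family, model):
        msa = self._family_msa(small_family)
        t1 = bootstrap_support(msa, model, replicates=15, seed=42)
        t2 = bootstrap_support(msa, model, replicates=15, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_family_topology_recovered(self, model):
        """With a long mature region NJ on estimated distances reproduces the
        generating topology (Robinson-Foulds distance 0)."""
        from actinofam.synthetic import FamilyConfig, simulate_family

        rng = np.random.default_rng(99)
        long_mature = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=1200)
        )
        cfg = FamilyConfig(
            n_leaves=12,
            tree_height=0.3,
            seed=5,
            ancestor="MNKALLVIALVFAVAQSMA" + "EDQKEQHKDNAEVKR" + long_mature,
        )
        proteins, _, truth = simulate_family(cfg)
        matures = {k: v[34:] for k, v in proteins.items()}
        msa = MultipleAlignment(
            ids=truth.leaf_labels, rows=[matures[l] for l in truth.leaf_labels]
        )
        est_tree = nj_tree(distance_matrix(msa, model))
        tns = dendropy.TaxonNamespace()
        true_t = dendropy.Tree.get(
            data=truth.tree_newick, schema="newick", taxon_namespace=tns
        )
        mine = dendropy.Tree.get(
            data=est_tree.to_newick(), schema="newick", taxon_namespace=tns
        )
        rf = dendropy.calculate.treecompare.symmetric_difference(
            true_t, mine, is_bipartitions_updated=False
        )
        assert rf == 0


def _all_nodes(node):
    yield node
    for c in node.children:
        yield from _all_nodes(c)


def _random_tree_newick(taxa, seed):
    """Random binary unrooted tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    nodes = [f"{t}:{rng.uniform(0.05, 0.4):.4f}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 0.4):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"


def _csv_of(dmat):
    import io as _io

    buf = _io.StringIO()
    buf.write("," + ",".join(dmat.ids) + "\n")
    for i, rid in enumerate(dmat.ids):
        buf.write(rid + "," + ",".join(str(v) for v in dmat.values[i]) + "\n")
    buf.seek(0)
    return buf
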