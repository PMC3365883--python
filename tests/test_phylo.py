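import io
import itertools

import dendropy
import numpy as np
import pytest

from coidiet import phylo
from coidiet.io_formats import TaxonPath, tree_from_newick_string


def leaf_distances(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        out[frozenset((a.label, b.label))] = pdm.patristic_distance(a, b)
    return out


def random_tree_distances(n: int, rng: np.random.Generator):
    """(ids, matrix) of leaf-to-leaf path lengths on a random binary tree."""
    ids = [f"T{i:02d}" for i in range(n)]
    dist = {i: {} for i in ids}
    clusters = [{i: 0.0} for i in ids]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters.pop(j), clusters.pop(i)
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for leaf_a, da in a.items():
            for leaf_b, db in b.items():
                d = da + la + db + lb
                dist[leaf_a][leaf_b] = dist[leaf_b][leaf_a] = d
        merged = {**{k: v + la for k, v in a.items()},
                  **{k: v + lb for k, v in b.items()}}
        clusters.append(merged)
    mat = np.array([[0.0 if x == y else dist[x][y] for y in ids] for x in ids])
    return ids, mat


def quartet_split(mat, i, j, k, l):
    """Four-point condition: the quartet split pairs the two taxa whose sum
    of within-pair distances is smallest."""
    sums = {
        frozenset((frozenset((i, j)), frozenset((k, l)))): mat[i, j] + mat[k, l],
        frozenset((frozenset((i, k)), frozenset((j, l)))): mat[i, k] + mat[j, l],
        frozenset((frozenset((i, l)), frozenset((j, k)))): mat[i, l] + mat[j, k],
    }
    return min(sums, key=sums.get)


class TestNJ:
    def test_three_taxon_closed_form(self):
        mat = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = phylo.nj_tree(mat, ["A", "B", "C"])
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_split_and_exact_lengths(self):
        # generating tree ((A:1,B:2):1,(C:1,D:1))
        ids = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0.0, 3.0, 3.0, 3.0],
                [3.0, 0.0, 4.0, 4.0],
                [3.0, 4.0, 0.0, 2.0],
                [3.0, 4.0, 2.0, 0.0],
            ]
        )
        tree = phylo.nj_tree(mat, ids)
        got = leaf_distances(tree)
        for a in range(4):
            for b in range(a + 1, 4):
                key = frozenset((ids[a], ids[b]))
                assert got[key] == pytest.approx(mat[a, b], abs=1e-12)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_additive_matrix_recovery(self, n):
        """On additive inputs NJ reproduces every leaf-to-leaf distance
        exactly, and its quartets agree with the four-point condition."""
        rng = np.random.default_rng(100 + n)
        ids, mat = random_tree_distances(n, rng)
        tree = phylo.nj_tree(mat, ids)
        got = leaf_distances(tree)
        for a in range(n):
            for b in range(a + 1, n):
                assert got[frozenset((ids[a], ids[b]))] == pytest.approx(
                    mat[a, b], rel=1e-9
                )
        # topology check via quartets against the input matrix
        njmat = np.array(
            [[0.0 if x == y else got[frozenset((x, y))] for y in ids] for x in ids]
        )
        for quartet in itertools.combinations(range(n), 4):
            assert quartet_split(mat, *quartet) == quartet_split(njmat, *quartet)

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        ids, mat = random_tree_distances(9, rng)
        ours = phylo.nj_tree(mat, ids)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids))
        t1 = skbio.TreeNode.read(
            io.StringIO(ours.as_string(schema="newick").replace("'", ""))
        )
        assert t1.compare_rfd(theirs) == 0.0

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        ids, mat = random_tree_distances(7, rng)
        tree1 = phylo.nj_tree(mat, ids)
        perm = rng.permutation(7)
        tree2 = phylo.nj_tree(mat[np.ix_(perm, perm)], [ids[p] for p in perm])
        assert leaf_distances(tree1) == pytest.approx(leaf_distances(tree2))

    def test_rejects_infinite_and_small_inputs(self):
        with pytest.raises(ValueError, match="saturated"):
            phylo.nj_tree(np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]]),
                          ["A", "B", "C"])
        with pytest.raises(ValueError):
            phylo.nj_tree(np.zeros((2, 2)), ["A", "B"])


class TestMidpointRoot:
    def test_root_splits_longest_path(self):
        tree = tree_from_newick_string("((A:1,B:2):1,(C:1,D:5):1);")
        phylo.midpoint_root(tree)
        # longest path B..D = 9 -> each side of the root is 4.5 deep
        pdm = {}
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            pdm[leaf.taxon.label] = depth
        assert pdm["D"] == pytest.approx(4.5)
        assert pdm["B"] == pytest.approx(4.5)

    def test_queries_excluded_from_midpoint(self):
        # the long query branch must not drag the root
        tree = tree_from_newick_string("((A:1,Q1:50):1,(B:1,C:2):1);")
        phylo.midpoint_root(tree, include_leaves=["A", "B", "C"])
        depths = {}
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = depth
        assert depths["A"] == pytest.approx(2.5)
        assert depths["C"] == pytest.approx(2.5)


class TestStrictCriterion:
    TAXONOMY = {
        "thor1": TaxonPath("Decapoda", "Hippolytidae", "Thor", "Thor amboinensis"),
        "thor2": TaxonPath("Decapoda", "Hippolytidae", "Thor", "Thor manningi"),
        "alph1": TaxonPath("Decapoda", "Alpheidae", "Synalpheus", "Synalpheus minus"),
        "alph2": TaxonPath("Decapoda", "Alpheidae", "Alpheus", "Alpheus armatus"),
        "pen1": TaxonPath("Decapoda", "Penaeidae", "Penaeus", "Penaeus duorarum"),
    }

    def test_query_sister_to_congeners_gets_genus(self):
        tree = tree_from_newick_string(
            "(((Q1:0.02,(thor1:0.04,thor2:0.04):0.01):0.1,"
            "(alph1:0.05,alph2:0.05):0.1):0.05,pen1:0.2);"
        )
        result = phylo.strict_criterion(tree, "Q1", self.TAXONOMY)
        assert (result.rank, result.taxon) == ("genus", "Thor")
        assert result.clade_size == 2

    def test_clade_spanning_families_resolves_to_order(self):
        tree = tree_from_newick_string(
            "((Q1:0.1,(thor1:0.08,alph1:0.08):0.02):0.1,"
            "(alph2:0.05,pen1:0.05):0.1);"
        )
        result = phylo.strict_criterion(tree, "Q1", self.TAXONOMY)
        assert (result.rank, result.taxon) == ("order", "Decapoda")

    def test_single_species_clade_gives_species(self):
        taxonomy = dict(self.TAXONOMY)
        taxonomy["thor1b"] = taxonomy["thor1"]
        tree = tree_from_newick_string(
            "(((Q1:0.01,(thor1:0.02,thor1b:0.02):0.01):0.1,thor2:0.1):0.1,"
            "(alph1:0.05,alph2:0.05):0.1,pen1:0.2);"
        )
        result = phylo.strict_criterion(tree, "Q1", taxonomy)
        assert (result.rank, result.taxon) == ("species", "Thor amboinensis")

    def test_other_queries_are_transparent(self):
        tree = tree_from_newick_string(
            "(((Q1:0.02,Q2:0.02):0.01,(thor1:0.04,thor2:0.04):0.01):0.1,"
            "((alph1:0.05,alph2:0.05):0.1,pen1:0.2):0.05);"
        )
        result = phylo.strict_criterion(
            tree, "Q1", self.TAXONOMY, transparent_ids=["Q2"]
        )
        assert (result.rank, result.taxon) == ("genus", "Thor")

    def test_missing_query_is_error(self):
        tree = tree_from_newick_string("((thor1:1,thor2:1):1,(alph1:1,pen1:1):1);")
        with pytest.raises(KeyError):
            phylo.strict_criterion(tree, "nope", self.TAXONOMY)

    def test_assigned_rank_never_finer_than_clade_unanimity(self, easy_fixture):
        """Post-hoc re-check on simulated trees: every strict assignment's
        clade really is unanimous at the assigned rank."""
        from coidiet import identify

        unresolved = easy_fixture.queries[:6]
        ctx = identify.TreeContext(
            easy_fixture.references, unresolved, easy_fixture.ref_taxonomy
        )
        for q in unresolved:
            res = ctx.assign(q.id)
            if res.rank == "none":
                continue
            tree = ctx.tree_for(q.id)
            labels = {
                easy_fixture.ref_taxonomy[l].label(res.rank)
                for l in self._clade_ref_leaves(tree, q.id, ctx.taxonomy)
            }
            assert labels == {res.taxon}

    @staticmethod
    def _clade_ref_leaves(tree, query_id, taxonomy):
        leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
        node = leaves[query_id]
        while node.parent_node is not None:
            node = node.parent_node
            refs = [
                l.taxon.label
                for l in node.leaf_iter()
                if l.taxon.label in taxonomy
            ]
            if refs:
                return refs
        return []
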