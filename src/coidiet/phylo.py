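"""Neighbor-joining trees and the tree-based "strict criterion".

NJ (Saitou & Nei) is implemented directly so that every choice is
bit-reproducible: the pair minimising the Q criterion

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined at each step, ties broken by the lexicographically smallest pair
of node labels (an internal node inherits the smallest leaf label beneath
it), branch lengths come from the standard two-point formulas with negative
estimates clamped to zero, and the final three nodes join at an unresolved
(trifurcating) root.

The strict criterion assigns an unknown leaf the taxon of the smallest
enclosing clade whose reference members are unanimous at some rank, testing
species first and coarsening from there.  Because NJ trees are unrooted,
the tree is first rooted at the midpoint of its longest reference-to-
reference path (query leaves are excluded from the midpoint computation so
unknowns cannot shift the root).  Other query leaves are "transparent":
they never vote in the unanimity test.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import RANKS, TaxonPath


@dataclasses.dataclass(frozen=True)
class StrictAssignment:
    query_id: str
    rank: str  # species | genus | family | order | none
    taxon: str
    clade_size: int  # reference leaves in the assigning clade


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: np.ndarray, ids: Sequence[str]) -> dendropy.Tree:
    """Classic NJ on a finite symmetric distance matrix (n >= 3)."""
    D = np.asarray(matrix, dtype=np.float64).copy()
    n = D.shape[0]
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if D.shape != (n, n) or len(ids) != n:
        raise ValueError("matrix/ids shape mismatch")
    if not np.isfinite(D).all():
        raise ValueError(
            "distance matrix contains non-finite entries; drop saturated taxa "
            "before tree building"
        )
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")

    taxa = dendropy.TaxonNamespace([str(i) for i in ids])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    labels: list[str] = []  # tie-break label = min leaf label in subtree
    for label in ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(str(label))
        nodes.append(node)
        labels.append(str(label))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        tie_i, tie_j = np.nonzero(Q <= qmin + tol)
        best = min(
            (
                (min(labels[active[a]], labels[active[b]]),
                 max(labels[active[a]], labels[active[b]]), a, b)
                for a, b in zip(tie_i.tolist(), tie_j.tolist())
                if a < b
            )
        )
        a, b = best[2], best[3]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_d
        D[active, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = dendropy.Node()
    for idx, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting restricted to reference leaves
# ---------------------------------------------------------------------------

def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _path_to_root(node: dendropy.Node):
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def _path_between(u: dendropy.Node, v: dendropy.Node):
    """Node path u..v and cumulative distances from u along it."""
    up_u = _path_to_root(u)
    up_v = _path_to_root(v)
    in_u = {id(x): k for k, x in enumerate(up_u)}
    lca_idx_v = next(k for k, x in enumerate(up_v) if id(x) in in_u)
    lca = up_v[lca_idx_v]
    first = up_u[: in_u[id(lca)] + 1]  # u ... lca
    second = up_v[:lca_idx_v][::-1]  # lca-child ... v
    path = first + second
    dists = [0.0]
    for k in range(1, len(path)):
        x, y = path[k - 1], path[k]
        if y is x.parent_node:
            edge = x.edge.length or 0.0
        else:
            edge = y.edge.length or 0.0
        dists.append(dists[-1] + edge)
    return path, dists


def midpoint_root(
    tree: dendropy.Tree, include_leaves: Iterable[str] | None = None
) -> dendropy.Tree:
    """Root (in place) at the midpoint of the longest path between the
    included leaves (default: all).  Ties broken by smallest label pair."""
    leaves = _leaf_map(tree)
    included = sorted(leaves if include_leaves is None else set(include_leaves))
    missing = [l for l in included if l not in leaves]
    if missing:
        raise ValueError(f"labels not in tree: {missing}")
    if len(included) < 2:
        raise ValueError("midpoint rooting needs at least two included leaves")

    pdm = tree.phylogenetic_distance_matrix()
    best = None
    for i, li in enumerate(included):
        ti = leaves[li].taxon
        for lj in included[i + 1 :]:
            d = pdm.patristic_distance(ti, leaves[lj].taxon)
            key = (-d, li, lj)
            if best is None or key < best[0]:
                best = (key, li, lj, d)
    _, lu, lv, total = best
    path, dists = _path_between(leaves[lu], leaves[lv])
    half = total / 2.0

    # Locate the point at distance `half` from u along the path.
    for k in range(1, len(path)):
        if dists[k] >= half - 1e-12:
            prev, nxt = path[k - 1], path[k]
            offset = half - dists[k - 1]  # distance from prev toward nxt
            break
    if nxt is prev.parent_node:  # walking up: edge belongs to prev
        child, parent = prev, nxt
        edge_len = child.edge.length or 0.0
        from_child = offset
    else:  # walking down: edge belongs to nxt, offset measured from parent
        child, parent = nxt, prev
        edge_len = child.edge.length or 0.0
        from_child = edge_len - offset
    from_child = min(max(from_child, 0.0), edge_len)
    if from_child <= 1e-12:
        root_node = child
    elif edge_len - from_child <= 1e-12:
        root_node = parent
    else:
        parent.remove_child(child)
        mid = parent.new_child(edge_length=edge_len - from_child)
        mid.add_child(child)
        child.edge.length = from_child
        root_node = mid
    if root_node.parent_node is not None:
        tree.reroot_at_node(root_node, update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Strict criterion
# ---------------------------------------------------------------------------

def strict_criterion(
    tree: dendropy.Tree,
    query_id: str,
    taxonomy: Mapping[str, TaxonPath],
    transparent_ids: Iterable[str] = (),
    reroot: bool = True,
) -> StrictAssignment:
    """Clade-unanimity assignment of one query leaf.

    Walks from the query's smallest reference-containing clade toward the
    root; within each clade tests ranks species -> order and assigns the
    finest rank at which every reference leaf carries the same non-empty
    label.  A rank that fails in a clade is never retested in an enclosing
    clade (a superset cannot restore unanimity).  Leaves listed in
    ``transparent_ids`` (other queries) never vote.
    """
    leaves = _leaf_map(tree)
    if query_id not in leaves:
        raise KeyError(f"query {query_id!r} is not a leaf of the tree")
    transparent = set(transparent_ids) | {query_id}
    if reroot:
        refs = [l for l in leaves if l in taxonomy and l not in transparent]
        midpoint_root(tree, include_leaves=refs)
        leaves = _leaf_map(tree)

    node = leaves[query_id]
    allowed = len(RANKS) - 1  # start at species
    seen: set[str] = set()
    while node.parent_node is not None:
        node = node.parent_node
        ref_leaves = [
            l
            for l in node.leaf_iter()
            if l.taxon.label not in transparent and l.taxon.label in taxonomy
        ]
        if not ref_leaves:
            continue
        for rank_idx in range(allowed, -1, -1):
            rank = RANKS[rank_idx]
            votes = {taxonomy[l.taxon.label].label(rank) for l in ref_leaves}
            if len(votes) == 1 and "" not in votes:
                return StrictAssignment(
                    query_id=query_id,
                    rank=rank,
                    taxon=votes.pop(),
                    clade_size=len(ref_leaves),
                )
            allowed = rank_idx - 1  # failed here, cannot succeed above
        if allowed < 0:
            break
    return StrictAssignment(query_id=query_id, rank="none", taxon="", clade_size=0)
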