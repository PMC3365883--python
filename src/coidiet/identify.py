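"""End-to-end taxonomic assignment of query sequences.

The decision procedure per query mirrors standard barcode-library practice:

1. rank all references by percent similarity over the aligned overlap
   (ties by K2P then id);
2. if the best hit lies under the species threshold (K2P x 100 < 3 by
   default) and every in-band hit agrees at species rank, assign that
   species — capped at the best reference's own taxonomic resolution, so a
   genus-only reference can never yield a species call;
3. if in-band hits disagree, assign the finest rank on which they are
   unanimous;
4. if no hit is in band, fall back to the tree-based strict criterion: the
   query is placed alone in an NJ tree with the reference library (each
   unknown gets its own tree, so co-occurring unknowns never influence one
   another).  A divergence above the species threshold precludes a
   species-level identification by definition, so strict-tree assignments
   are capped at genus rank;
5. if the tree yields no unanimous clade, the query stays unidentified.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from . import phylo
from .distances import AnchorPanel, PairwiseComparison, compare_records
from .io_formats import RANKS, SeqRecord, TaxonPath

#: Hits within this many percentage points of the best similarity count as ties.
TIE_BAND_PCT = 0.01


@dataclasses.dataclass(frozen=True)
class Hit:
    ref_id: str
    similarity_pct: float
    k2p: float
    overlap_sites: int
    comparison: PairwiseComparison | None = None

    @property
    def k2p_pct(self) -> float:
        return 100.0 * self.k2p


@dataclasses.dataclass(frozen=True)
class Assignment:
    query_id: str
    method: str  # threshold | strict-tree | none
    rank: str  # species | genus | family | order | none
    taxon: str
    best_ref_id: str
    best_similarity_pct: float
    best_k2p_pct: float
    n_ties: int


def _sort_hits(hits: list[Hit]) -> list[Hit]:
    return sorted(hits, key=lambda h: (-h.similarity_pct, h.k2p, h.ref_id))


def best_matches(
    query: SeqRecord,
    references: Sequence[SeqRecord],
    top_n: int = 10,
    panel: AnchorPanel | None = None,
) -> list[Hit]:
    """Ranked best matches of one query against the reference library.

    With a prebuilt :class:`AnchorPanel` the comparisons are vectorised;
    otherwise each pair is aligned exactly.
    """
    if not references:
        raise ValueError("empty reference set")
    hits: list[Hit] = []
    if panel is not None:
        ids, overlap, similarity, k2p = panel.k2p_row(
            query.id, against=[r.id for r in references]
        )
        for rid, ov, sim, d in zip(ids, overlap, similarity, k2p):
            if ov == 0:
                continue
            hits.append(Hit(rid, float(sim), float(d), int(ov)))
    else:
        for ref in references:
            comp = compare_records(query, ref)
            hits.append(
                Hit(ref.id, comp.similarity_pct, comp.k2p, comp.overlap_sites, comp)
            )
    return _sort_hits(hits)[:top_n]


def _finest_unanimous_rank(taxa: Sequence[TaxonPath]) -> tuple[str, str]:
    """(rank, label) of the finest rank where all paths share one non-empty
    label, or ('none', '')."""
    for rank in reversed(RANKS):
        votes = {t.label(rank) for t in taxa}
        if len(votes) == 1 and "" not in votes:
            return rank, votes.pop()
    return "none", ""


def assign(
    query: SeqRecord,
    hits: Sequence[Hit],
    taxonomy: Mapping[str, TaxonPath],
    tree_context: "TreeContext | None" = None,
    species_threshold_pct: float = 3.0,
) -> Assignment:
    """Assign one query from its ranked hits (threshold rule + fallback)."""
    if not hits:
        raise ValueError(f"no hits for query {query.id!r}")
    best = hits[0]
    n_ties = sum(
        1 for h in hits if best.similarity_pct - h.similarity_pct <= TIE_BAND_PCT
    )
    in_band = [h for h in hits if h.k2p_pct < species_threshold_pct]
    if in_band:
        rank, taxon = _finest_unanimous_rank([taxonomy[h.ref_id] for h in in_band])
        method = "threshold" if rank != "none" else "none"
        return Assignment(
            query_id=query.id,
            method=method,
            rank=rank,
            taxon=taxon,
            best_ref_id=best.ref_id,
            best_similarity_pct=best.similarity_pct,
            best_k2p_pct=best.k2p_pct,
            n_ties=n_ties,
        )
    if tree_context is not None:
        strict = tree_context.assign(query.id)
        rank, taxon = strict.rank, strict.taxon
        if rank == "species":
            # Above the species threshold a species-level call is not
            # defensible; cap at the genus of the unanimous clade.
            clade_genus = _genus_of_species(taxonomy, taxon)
            rank, taxon = ("genus", clade_genus) if clade_genus else ("none", "")
        if rank != "none":
            return Assignment(
                query_id=query.id,
                method="strict-tree",
                rank=rank,
                taxon=taxon,
                best_ref_id=best.ref_id,
                best_similarity_pct=best.similarity_pct,
                best_k2p_pct=best.k2p_pct,
                n_ties=n_ties,
            )
    return Assignment(
        query_id=query.id,
        method="none",
        rank="none",
        taxon="",
        best_ref_id=best.ref_id,
        best_similarity_pct=best.similarity_pct,
        best_k2p_pct=best.k2p_pct,
        n_ties=n_ties,
    )


def _genus_of_species(taxonomy: Mapping[str, TaxonPath], species: str) -> str:
    for path in taxonomy.values():
        if path.species == species:
            return path.genus
    # A binomial's first token is its genus by construction.
    return species.split(" ")[0] if " " in species else ""


class TreeContext:
    """Strict-criterion trees for the queries the threshold rule left open.

    One NJ tree is built per unresolved query, over that query plus the full
    reference library.  Placing each unknown alone keeps queries perfectly
    transparent to each other: a batch of conspecific unknowns (the common
    case for an unreferenced prey species) can never cluster into a
    query-only clade that drags them all to the wrong side of a reference
    split, and no query-query distance — undefined when two short fragments
    cover disjoint parts of the barcode — is ever required.

    The shared reference-reference distance block is computed once;
    references saturated against each other are dropped up front, and
    references saturated against a particular query are dropped from that
    query's tree only.
    """

    def __init__(
        self,
        references: Sequence[SeqRecord],
        queries: Sequence[SeqRecord],
        taxonomy: Mapping[str, TaxonPath],
        panel: AnchorPanel | None = None,
    ) -> None:
        self.taxonomy = dict(taxonomy)
        self.query_ids = [q.id for q in queries]
        if panel is None:
            panel = AnchorPanel(list(references) + list(queries))
        self.panel = panel
        self.ref_ids = [r.id for r in references]
        idx = np.array([panel.index[r] for r in self.ref_ids])
        ref_matrix = panel.full_matrix(allow_missing=True)[np.ix_(idx, idx)]
        keep = _drop_bad_rows(ref_matrix, self.ref_ids)
        self.ref_ids = [self.ref_ids[i] for i in keep]
        self.ref_matrix = ref_matrix[np.ix_(keep, keep)]
        self._cache: dict[str, phylo.StrictAssignment] = {}

    def tree_for(self, query_id: str):
        """Midpoint-rooted NJ tree of the query plus its usable references,
        or None when fewer than two references can be placed against it."""
        _, overlap, _, k2p = self.panel.k2p_row(query_id, against=self.ref_ids)
        usable = np.flatnonzero((overlap > 0) & np.isfinite(k2p))
        if usable.size < 2:
            return None
        ids = [self.ref_ids[i] for i in usable] + [query_id]
        n = usable.size
        matrix = np.zeros((n + 1, n + 1))
        matrix[:n, :n] = self.ref_matrix[np.ix_(usable, usable)]
        matrix[n, :n] = matrix[:n, n] = k2p[usable]
        tree = phylo.nj_tree(matrix, ids)
        phylo.midpoint_root(tree, include_leaves=ids[:-1])
        return tree

    def assign(self, query_id: str) -> phylo.StrictAssignment:
        if query_id in self._cache:
            return self._cache[query_id]
        tree = self.tree_for(query_id)
        if tree is None:
            result = phylo.StrictAssignment(query_id, "none", "", 0)
        else:
            result = phylo.strict_criterion(
                tree, query_id, self.taxonomy, reroot=False
            )
        self._cache[query_id] = result
        return result


def _drop_bad_rows(matrix: np.ndarray, ids: Sequence[str]) -> list[int]:
    """Indices to keep so the matrix is fully finite; rows involved in the
    most saturated/missing cells go first (ties by id)."""
    keep = list(range(len(ids)))
    while True:
        sub = matrix[np.ix_(keep, keep)]
        bad = ~np.isfinite(sub)
        np.fill_diagonal(bad, False)
        if not bad.any():
            return keep
        counts = bad.sum(axis=1)
        victim = max(range(len(keep)), key=lambda k: (counts[k], ids[keep[k]]))
        del keep[victim]


@dataclasses.dataclass
class BatchReport:
    n_queries: int
    by_method: dict[str, int]
    by_rank: dict[str, int]


def identify_batch(
    queries: Sequence[SeqRecord],
    references: Sequence[SeqRecord],
    taxonomy: Mapping[str, TaxonPath],
    species_threshold_pct: float = 3.0,
    top_n: int = 10,
) -> tuple[list[Assignment], BatchReport]:
    """Assign every query; deterministic given the inputs.

    Stage 1 ranks hits via a shared anchor panel; stage 2 builds one joint
    NJ tree for the queries left unresolved by the threshold rule.
    """
    if not queries:
        return [], BatchReport(0, {}, {})
    if not references:
        raise ValueError("empty reference set")
    panel = AnchorPanel(list(references) + list(queries))
    hit_lists = {
        q.id: best_matches(q, references, top_n=top_n, panel=panel) for q in queries
    }
    unresolved = [
        q
        for q in queries
        if hit_lists[q.id]
        and not any(h.k2p_pct < species_threshold_pct for h in hit_lists[q.id])
    ]
    tree_context = (
        TreeContext(references, unresolved, taxonomy, panel=panel)
        if unresolved
        else None
    )
    assignments = [
        assign(
            q,
            hit_lists[q.id],
            taxonomy,
            tree_context=tree_context,
            species_threshold_pct=species_threshold_pct,
        )
        for q in queries
    ]
    by_method: dict[str, int] = {}
    by_rank: dict[str, int] = {}
    for a in assignments:
        by_method[a.method] = by_method.get(a.method, 0) + 1
        by_rank[a.rank] = by_rank.get(a.rank, 0) + 1
    return assignments, BatchReport(len(assignments), by_method, by_rank)


def prey_records(
    assignments: Sequence[Assignment], taxonomy: Mapping[str, TaxonPath]
):
    """Identified assignments as composition-ready prey records.

    Each assignment resolved to at least order rank becomes a
    :class:`~coidiet.composition.PreyRecord` whose taxon path is truncated
    at the assigned rank (the coarser ranks are filled from any reference
    path carrying the assigned label)."""
    from .composition import PreyRecord

    prey = []
    for a in assignments:
        if a.rank == "none":
            continue
        template = next(
            (p for p in taxonomy.values() if p.label(a.rank) == a.taxon), None
        )
        if template is None:
            continue
        fields = {}
        for rank in RANKS:
            fields[rank] = template.label(rank)
            if rank == a.rank:
                break
        prey.append(PreyRecord(id=a.query_id, taxon=TaxonPath(**fields)))
    return prey


def assignments_to_rows(assignments: Sequence[Assignment]) -> list[dict]:
    """TSV rows with the reported display precision (2-decimal similarity)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "query_id": a.query_id,
                "method": a.method,
                "rank": a.rank,
                "taxon": a.taxon,
                "best_ref_id": a.best_ref_id,
                "similarity_pct": f"{a.best_similarity_pct:.2f}",
                "k2p_pct": "inf" if math.isinf(a.best_k2p_pct) else f"{a.best_k2p_pct:.4f}",
                "n_ties": a.n_ties,
            }
        )
    return rows
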