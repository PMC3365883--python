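import numpy as np
import pytest

from coidiet import identify, synthetic_data as sd
from coidiet.io_formats import SeqRecord, TaxonPath


def ref(rid, seq, order="Perciformes", family="Gobiidae", genus="Coryphopterus",
        species="Coryphopterus eidolon"):
    return SeqRecord(
        id=rid, sequence=seq, role="reference",
        taxon=TaxonPath(order, family, genus, species),
    )


RNG = np.random.default_rng(123)
BASE = "".join(RNG.choice(list("ACGT"), 658))


def mutated(seq, positions, swap={"A": "G", "G": "A", "C": "T", "T": "C"}):
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestBestMatches:
    def test_identical_reference_ranks_first_at_100(self):
        refs = [
            ref("r1", BASE),
            ref("r2", mutated(BASE, range(0, 658, 10)), species="Coryphopterus thrix"),
        ]
        query = SeqRecord(id="q", sequence=BASE[20:620])
        hits = identify.best_matches(query, refs)
        assert hits[0].ref_id == "r1"
        assert hits[0].similarity_pct == 100.0

    def test_equidistant_references_tie_lexicographically(self):
        refs = [
            ref("rB", mutated(BASE, [5]), species="Coryphopterus thrix"),
            ref("rA", mutated(BASE, [11])),
        ]
        query = SeqRecord(id="q", sequence=BASE)
        hits = identify.best_matches(query, refs)
        assert [h.ref_id for h in hits] == ["rA", "rB"]
        taxonomy = {r.id: r.taxon for r in refs}
        result = identify.assign(query, hits, taxonomy)
        assert result.n_ties == 2

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            identify.best_matches(SeqRecord(id="q", sequence="ACGT"), [])


class TestAssign:
    def test_close_match_to_genus_only_reference_caps_at_genus(self):
        genus_only = SeqRecord(
            id="syn1", sequence=BASE, role="reference",
            taxon=TaxonPath("Decapoda", "Alpheidae", "Synalpheus"),
        )
        query = SeqRecord(id="q", sequence=mutated(BASE, [3, 40, 100, 200, 300]))
        hits = identify.best_matches(query, [genus_only])
        result = identify.assign(query, hits, {"syn1": genus_only.taxon})
        assert result.method == "threshold"
        assert (result.rank, result.taxon) == ("genus", "Synalpheus")
        assert result.best_similarity_pct > 99

    def test_in_band_species_disagreement_falls_to_finest_unanimous_rank(self):
        refs = [
            ref("r1", mutated(BASE, [1])),
            ref("r2", mutated(BASE, [2]), species="Coryphopterus thrix"),
        ]
        query = SeqRecord(id="q", sequence=BASE)
        hits = identify.best_matches(query, refs)
        result = identify.assign(query, hits, {r.id: r.taxon for r in refs})
        assert result.method == "threshold"
        assert (result.rank, result.taxon) == ("genus", "Coryphopterus")

    def test_simulated_easy_queries_hit_true_species(self, easy_fixture, easy_assignments):
        assignments, _ = easy_assignments
        truth = easy_fixture.truth.set_index("query_id")
        for a in assignments:
            row = truth.loc[a.query_id]
            if row["category"] != "dark":
                assert a.method == "threshold"
                assert (a.rank, a.taxon) == ("species", row["species"])

    def test_dark_queries_resolve_by_tree_to_correct_genus(self, easy_fixture, easy_assignments):
        """A query whose species is absent from the references: no in-band
        hit, strict-tree fallback, genus of its referenced congeners."""
        assignments, _ = easy_assignments
        truth = easy_fixture.truth.set_index("query_id")
        dark = [a for a in assignments if truth.loc[a.query_id, "category"] == "dark"]
        assert dark, "fixture must contain dark queries"
        for a in dark:
            assert a.rank != "species"
            if a.method == "strict-tree" and a.rank == "genus":
                assert a.taxon == truth.loc[a.query_id, "genus"]

    def test_no_assignment_contradicts_truth_at_coarser_ranks(
        self, easy_fixture, easy_assignments
    ):
        assignments, _ = easy_assignments
        truth = easy_fixture.truth.set_index("query_id")
        for a in assignments:
            if a.rank == "none":
                continue
            row = truth.loc[a.query_id]
            assert a.taxon == row[a.rank]

    def test_raising_threshold_never_demotes_species(self, easy_fixture):
        results = {}
        for thr in (2.0, 3.0, 4.0):
            assignments, _ = identify.identify_batch(
                easy_fixture.queries,
                easy_fixture.references,
                easy_fixture.ref_taxonomy,
                species_threshold_pct=thr,
            )
            results[thr] = {a.query_id: a.rank for a in assignments}
        rank_order = {"none": 0, "order": 1, "family": 2, "genus": 3, "species": 4}
        for qid in results[2.0]:
            if results[2.0][qid] == "species":
                assert rank_order[results[3.0][qid]] >= rank_order[results[2.0][qid]]
            if results[3.0][qid] == "species":
                assert rank_order[results[4.0][qid]] >= rank_order[results[3.0][qid]]


class TestIdentifyBatch:
    def test_trivial_identical_fixture(self):
        refs = [ref("r1", BASE)]
        queries = [SeqRecord(id=f"q{i}", sequence=BASE) for i in range(3)]
        assignments, report = identify.identify_batch(
            queries, refs, {"r1": refs[0].taxon}
        )
        assert report.by_method == {"threshold": 3}
        assert all(a.rank == "species" for a in assignments)

    def test_empty_query_set(self):
        assignments, report = identify.identify_batch(
            [], [ref("r1", BASE)], {"r1": None}
        )
        assert assignments == [] and report.n_queries == 0

    def test_method_distribution_matches_construction(self, easy_fixture, easy_assignments):
        assignments, report = easy_assignments
        truth = easy_fixture.truth
        n_dark = (truth["category"] == "dark").sum()
        assert report.by_method.get("strict-tree", 0) + report.by_method.get(
            "none", 0
        ) == n_dark
        assert report.by_method.get("threshold", 0) == len(truth) - n_dark

    def test_bookkeeping_conserved(self, easy_assignments):
        assignments, report = easy_assignments
        assert sum(report.by_method.values()) == report.n_queries == len(assignments)


class TestPreyRecords:
    def test_paths_truncate_at_assigned_rank(self):
        taxonomy = {
            "r1": TaxonPath("Decapoda", "Hippolytidae", "Thor", "Thor amboinensis")
        }
        a = identify.Assignment(
            query_id="q", method="strict-tree", rank="genus", taxon="Thor",
            best_ref_id="r1", best_similarity_pct=93.18, best_k2p_pct=7.2, n_ties=1,
        )
        (prey,) = identify.prey_records([a], taxonomy)
        assert prey.taxon.genus == "Thor" and prey.taxon.species == ""
        assert prey.taxon.family == "Hippolytidae"

    def test_unassigned_queries_are_skipped(self):
        a = identify.Assignment(
            query_id="q", method="none", rank="none", taxon="",
            best_ref_id="r1", best_similarity_pct=70.0, best_k2p_pct=40.0, n_ties=1,
        )
        assert identify.prey_records([a], {}) == []
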