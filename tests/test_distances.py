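import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coidiet import distances as dist
from coidiet import synthetic_data as sd
from coidiet.io_formats import SeqRecord


def _oracle_semiglobal_score(a, b, match=1.0, mismatch=-1.0, open_=-10.0, ext=-1.0):
    """Independent three-state affine DP with free end gaps (tiny inputs)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0  # leading gap in b, free
    for j in range(1, m + 1):
        Iy[0][j] = 0.0  # leading gap in a, free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext, Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + ext, Ix[i][j - 1] + open_)
    best = NEG
    for i in range(n + 1):  # trailing gap in b free
        best = max(best, M[i][m], Ix[i][m], Iy[i][m])
    for j in range(m + 1):  # trailing gap in a free
        best = max(best, M[n][j], Ix[n][j], Iy[n][j])
    return best


class TestAlignOverlap:
    def test_exact_substring_aligns_gapless_at_no_cost(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), 658))
        query = ref[100:400]
        pair = dist.align_overlap(query, ref)
        comp = dist.k2p_distance(pair)
        assert comp.overlap_sites == 300
        assert comp.transitions == comp.transversions == 0
        assert comp.internal_gaps == 0
        assert pair.score == 300  # every overlap column matches, end gaps free

    def test_identical_sequences_full_overlap(self):
        pair = dist.align_overlap("ACGTACGT", "ACGTACGT")
        comp = dist.k2p_distance(pair)
        assert comp.overlap_sites == 8 and comp.p_distance == 0

    def test_substring_with_three_substitutions(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), 658))
        frag = list(ref[50:350])
        for pos in (10, 150, 299):
            frag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[pos]]
        comp = dist.k2p_distance(dist.align_overlap("".join(frag), ref))
        assert comp.overlap_sites == 300
        assert comp.transitions + comp.transversions == 3
        assert comp.internal_gaps == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=12),
        b=st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_score_matches_bruteforce_dp_oracle(self, a, b):
        pair = dist.align_overlap(a, b)
        assert pair.score == pytest.approx(_oracle_semiglobal_score(a, b))


def hand_aligned(a: str, b: str) -> dist.AlignedPair:
    """Positionally aligned pair, as written down by hand."""
    return dist.AlignedPair("query", "ref", a, b, score=float("nan"))


class TestK2P:
    def test_single_transition_hand_count(self):
        comp = dist.k2p_distance(hand_aligned("AAAAAAAA", "GAAAAAAA"))
        assert comp.transitions == 1 and comp.transversions == 0
        assert comp.k2p == pytest.approx(-0.5 * math.log(0.75), abs=1e-9)
        assert comp.k2p == pytest.approx(0.143841, abs=1e-6)

    def test_single_transversion_hand_count(self):
        comp = dist.k2p_distance(hand_aligned("AAAA", "ACAA"))
        assert comp.transitions == 0 and comp.transversions == 1
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.5)
        assert comp.k2p == pytest.approx(expected, abs=1e-9)
        assert comp.k2p == pytest.approx(0.317128, abs=1e-6)

    def test_identical_sequences_zero_distance(self):
        comp = dist.k2p_distance(dist.align_overlap("ACGTACGT", "ACGTACGT"))
        assert comp.k2p == 0.0 and comp.similarity_pct == 100.0

    def test_symmetry_under_swap(self):
        a, b = "ACGTTGCAACGT", "ACGTAGCATCGT"
        fwd = dist.k2p_distance(dist.align_overlap(a, b, "x", "y"))
        rev = dist.k2p_distance(dist.align_overlap(b, a, "y", "x"))
        for field in ("overlap_sites", "transitions", "transversions", "k2p"):
            assert getattr(fwd, field) == getattr(rev, field)

    def test_saturated_pair_reports_infinity(self):
        # all transversions: 1 - 2Q < 0
        comp = dist.k2p_distance(hand_aligned("AAAA", "CCCC"))
        assert comp.saturated and math.isinf(comp.k2p)

    def test_ambiguous_sites_pairwise_deleted(self):
        comp = dist.k2p_distance(hand_aligned("ANGT", "AAGT"))
        assert comp.overlap_sites == 3 and comp.p_distance == 0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ts=st.integers(min_value=0, max_value=20),
        tv=st.integers(min_value=0, max_value=20),
        extra=st.integers(min_value=1, max_value=500),
    )
    def test_k2p_dominates_p_distance(self, ts, tv, extra):
        overlap = ts + tv + extra
        d = dist.k2p_from_counts(ts, tv, overlap)
        if math.isfinite(d):
            assert d >= (ts + tv) / overlap - 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_all_zero(self):
        records = [SeqRecord(id=f"r{i}", sequence="ACGT" * 20) for i in range(4)]
        result = dist.distance_matrix(records)
        assert np.all(result.matrix == 0)

    def test_symmetric_with_zero_diagonal(self, easy_fixture):
        result = dist.distance_matrix(easy_fixture.references[:8], method="anchor")
        assert np.array_equal(result.matrix, result.matrix.T)
        assert np.all(np.diag(result.matrix) == 0)
        assert result.min <= result.mean <= result.max

    def test_conspecific_panels_recover_low_divergence(self):
        """Panels of 30 conspecific haplotypes simulated at 0.054% expected
        pairwise divergence: the mean off-diagonal K2P lands within 3 SE of
        that value (SE over independent species, since conspecific distances
        share branches within one species)."""
        cfg = sd.SimConfig(
            seed=30, n_orders=1, families_per_order=1, genera_per_family=6,
            species_per_genus=2, haplotypes_per_species=30,
            intraspecific_div=0.00054, interspecific_div=0.05,
        )
        lib = sd.simulate_reference_library(cfg, sd.simulate_taxonomy(cfg))
        by_species = {}
        for rec in lib:
            by_species.setdefault(rec.taxon.species, []).append(rec)
        means = []
        for panel in by_species.values():
            result = dist.distance_matrix(panel, method="anchor")
            means.append(result.mean)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.00054) <= 3 * se

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            dist.distance_matrix([SeqRecord(id="a", sequence="ACGT")])


class TestAnchorPanel:
    def test_matches_exact_pairwise_on_indel_free_data(self, easy_fixture):
        records = easy_fixture.references[:6] + easy_fixture.queries[:6]
        panel = dist.AnchorPanel(records)
        for i in range(0, len(records), 3):
            for j in range(i + 1, len(records), 2):
                exact = dist.compare_records(records[i], records[j])
                fast = panel.compare(records[i].id, records[j].id)
                assert (fast.overlap_sites, fast.transitions, fast.transversions) == (
                    exact.overlap_sites, exact.transitions, exact.transversions
                )

    def test_missing_overlap_reported_as_nan(self):
        rng = np.random.default_rng(42)
        anchor = SeqRecord(id="anchor", sequence="".join(rng.choice(list("ACGT"), 400)))
        left = SeqRecord(id="left", sequence=anchor.sequence[:80])
        right = SeqRecord(id="right", sequence=anchor.sequence[300:])
        panel = dist.AnchorPanel([anchor, left, right])
        mat = panel.full_matrix(allow_missing=True)
        i, j = panel.index["left"], panel.index["right"]
        assert math.isnan(mat[i, j])
        with pytest.raises(dist.NoOverlapError):
            panel.full_matrix()
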