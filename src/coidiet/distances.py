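"""Pairwise distances between barcode sequences.

A query fragment is aligned to a full-length reference with a semi-global
(free end-gap) affine alignment, and transition/transversion counts over the
aligned overlap give the p-distance, percent similarity and the Kimura
two-parameter (K2P) distance

    d = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over the overlap
(pairwise deletion: sites with an ambiguity code or a gap in either sequence
are excluded from all counts).

Two comparison engines are provided with identical semantics on indel-free
data:

* :func:`align_overlap` + :func:`k2p_distance` — exact affine pairwise
  alignment (the reference primitive, O(len^2) per pair);
* :class:`AnchorPanel` — every sequence is aligned once onto a common anchor
  coordinate system and all pairwise counts are then vectorised.  Mitochondrial
  COI barcodes are effectively indel-free (an internal gap is a pseudogene
  warning sign, not an expected event), so the projection is exact for this
  locus; batch stages use it to keep thousands of comparisons fast.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SeqRecord

# Base encoding: A,C,G,T -> 0..3; ambiguity codes -> 4; gap/absent -> 5.
# Transitions (A<->G, C<->T) are exactly the pairs whose codes XOR to an
# even number, which keeps the vectorised count branch-free.
_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip("ACGT", range(4)):
    _CODE[ord(_b)] = _c
_GAP = np.uint8(5)
_CODE[ord("-")] = _GAP


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class NoOverlapError(ValueError):
    """Raised when two sequences share no unambiguous aligned site."""


@dataclasses.dataclass(frozen=True)
class AlignedPair:
    query_id: str
    ref_id: str
    query_aligned: str
    ref_aligned: str
    score: float


@dataclasses.dataclass(frozen=True)
class PairwiseComparison:
    """Counts and distances over the aligned overlap of one sequence pair."""

    query_id: str
    ref_id: str
    overlap_sites: int
    transitions: int
    transversions: int
    internal_gaps: int

    @property
    def p_distance(self) -> float:
        return (self.transitions + self.transversions) / self.overlap_sites

    @property
    def similarity_pct(self) -> float:
        return 100.0 * (1.0 - self.p_distance)

    @property
    def k2p(self) -> float:
        return k2p_from_counts(
            self.transitions, self.transversions, self.overlap_sites
        )

    @property
    def saturated(self) -> bool:
        return math.isinf(self.k2p)

    def swapped(self) -> "PairwiseComparison":
        return dataclasses.replace(
            self, query_id=self.ref_id, ref_id=self.query_id
        )


def k2p_from_counts(transitions: int, transversions: int, overlap: int) -> float:
    """Closed-form K2P distance from substitution counts.

    Returns ``inf`` when the logarithm arguments are non-positive
    (saturation), mirroring how distance software flags such pairs.
    """
    if overlap < 1:
        raise NoOverlapError("overlap_sites must be >= 1")
    P = transitions / overlap
    Q = transversions / overlap
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


# ---------------------------------------------------------------------------
# Exact pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Affine: Biopython's open_gap_score applies to the first gap position.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_overlap(
    query_seq: str,
    ref_seq: str,
    query_id: str = "query",
    ref_id: str = "ref",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignedPair:
    """Optimal semi-global alignment of two sequences.

    Terminal gaps are unpenalised, so a fragment aligns to its containing
    region of a full-length barcode at no cost.  The first optimal traceback
    reported by the dynamic program is taken, which is deterministic.
    """
    if not query_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(query_seq.upper(), ref_seq.upper())[0]
    q_aln, r_aln = str(alignment[0]), str(alignment[1])
    return AlignedPair(query_id, ref_id, q_aln, r_aln, alignment.score)


def _count_gap_openings(codes: np.ndarray, lo: int, hi: int) -> int:
    """Gap openings of one aligned row strictly inside columns [lo, hi]."""
    region = codes[lo : hi + 1] == _GAP
    if not region.any():
        return 0
    return int(region[0]) + int((region[1:] & ~region[:-1]).sum())


def k2p_distance(pair: AlignedPair) -> PairwiseComparison:
    """Substitution counts and distances over the aligned overlap.

    The overlap spans the first to last alignment column where both rows
    carry a base; within it, sites with an ambiguity code or gap in either
    row are excluded from the counts (pairwise deletion) while gap openings
    are counted separately as an indel diagnostic.
    """
    q = encode(pair.query_aligned)
    r = encode(pair.ref_aligned)
    both = (q != _GAP) & (r != _GAP)
    if not both.any():
        raise NoOverlapError(
            f"no aligned overlap between {pair.query_id!r} and {pair.ref_id!r}"
        )
    cols = np.flatnonzero(both)
    lo, hi = int(cols[0]), int(cols[-1])
    valid = (q < 4) & (r < 4)
    diff = valid & (q != r)
    xor = q ^ r
    transitions = int((diff & (xor % 2 == 0)).sum())
    transversions = int((diff & (xor % 2 == 1)).sum())
    overlap = int(valid.sum())
    if overlap == 0:
        raise NoOverlapError(
            f"no unambiguous overlap between {pair.query_id!r} and {pair.ref_id!r}"
        )
    internal_gaps = _count_gap_openings(q, lo, hi) + _count_gap_openings(r, lo, hi)
    return PairwiseComparison(
        query_id=pair.query_id,
        ref_id=pair.ref_id,
        overlap_sites=overlap,
        transitions=transitions,
        transversions=transversions,
        internal_gaps=internal_gaps,
    )


def compare_records(query: SeqRecord, ref: SeqRecord, **aligner_kwargs) -> PairwiseComparison:
    """Align two records semi-globally and compute their comparison."""
    return k2p_distance(
        align_overlap(query.sequence, ref.sequence, query.id, ref.id, **aligner_kwargs)
    )


# ---------------------------------------------------------------------------
# Anchor-projection panel
# ---------------------------------------------------------------------------

class AnchorPanel:
    """All-vs-all comparisons via projection onto a common anchor.

    The longest sequence (ties broken by lexicographically smallest id) is
    the anchor; every other sequence is aligned to it once and stored as a
    row over anchor coordinates.  Bases the alignment places opposite an
    anchor gap (insertions) are dropped and counted in
    :attr:`insertion_events`; on indel-free data the projection reproduces
    the exact pairwise alignment for every pair.
    """

    def __init__(self, records: Sequence[SeqRecord], **aligner_kwargs) -> None:
        if not records:
            raise ValueError("empty record list")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in panel")
        self.ids: list[str] = ids
        self.index = {rid: i for i, rid in enumerate(ids)}
        anchor = min(records, key=lambda r: (-len(r.sequence), r.id))
        self.anchor_id = anchor.id
        L = len(anchor.sequence)
        self.rows = np.full((len(records), L), _GAP, dtype=np.uint8)
        self.spans = np.zeros((len(records), 2), dtype=np.int64)  # [lo, hi]
        self.insertion_events = 0
        anchor_codes = encode(anchor.sequence)
        for i, rec in enumerate(records):
            if rec.id == anchor.id:
                self.rows[i] = anchor_codes
                self.spans[i] = (0, L - 1)
                continue
            pair = align_overlap(
                rec.sequence, anchor.sequence, rec.id, anchor.id, **aligner_kwargs
            )
            q = encode(pair.query_aligned)
            r = encode(pair.ref_aligned)
            keep = r != _GAP
            self.insertion_events += int(((~keep) & (q != _GAP)).sum())
            projected = q[keep]
            covered = np.flatnonzero(projected != _GAP)
            if covered.size == 0:
                raise NoOverlapError(
                    f"{rec.id!r} does not align to anchor {anchor.id!r}"
                )
            self.rows[i] = projected
            self.spans[i] = (int(covered[0]), int(covered[-1]))

    def __len__(self) -> int:
        return len(self.ids)

    def _counts(self, i: int, idx: np.ndarray):
        q = self.rows[i]
        R = self.rows[idx]
        valid = (q < 4) & (R < 4)
        diff = valid & (q != R)
        xor = q ^ R
        ts = (diff & (xor % 2 == 0)).sum(axis=1)
        tv = (diff & (xor % 2 == 1)).sum(axis=1)
        overlap = valid.sum(axis=1)
        return overlap, ts, tv

    def compare(self, id_i: str, id_j: str) -> PairwiseComparison:
        i, j = self.index[id_i], self.index[id_j]
        overlap, ts, tv = self._counts(i, np.array([j]))
        if overlap[0] == 0:
            raise NoOverlapError(f"no overlap between {id_i!r} and {id_j!r}")
        lo = int(max(self.spans[i, 0], self.spans[j, 0]))
        hi = int(min(self.spans[i, 1], self.spans[j, 1]))
        gaps = 0
        if hi >= lo:
            gaps = _count_gap_openings(self.rows[i], lo, hi) + _count_gap_openings(
                self.rows[j], lo, hi
            )
        return PairwiseComparison(
            query_id=id_i,
            ref_id=id_j,
            overlap_sites=int(overlap[0]),
            transitions=int(ts[0]),
            transversions=int(tv[0]),
            internal_gaps=gaps,
        )

    def k2p_row(self, id_i: str, against: Sequence[str] | None = None):
        """Vectorised overlap/similarity/K2P of one sequence against many.

        Returns ``(ids, overlap, similarity_pct, k2p)`` arrays; pairs with
        zero overlap get similarity NaN and K2P inf.
        """
        i = self.index[id_i]
        others = list(against) if against is not None else [
            rid for rid in self.ids if rid != id_i
        ]
        idx = np.array([self.index[rid] for rid in others], dtype=np.int64)
        overlap, ts, tv = self._counts(i, idx)
        return others, overlap, *_vector_k2p(overlap, ts, tv)

    def full_matrix(self, allow_missing: bool = False) -> np.ndarray:
        """Square K2P matrix; pairs with no unambiguous overlap either raise
        or (``allow_missing=True``) are reported as NaN."""
        n = len(self.ids)
        mat = np.zeros((n, n), dtype=np.float64)
        for i in range(n - 1):
            idx = np.arange(i + 1, n)
            overlap, ts, tv = self._counts(i, idx)
            if (overlap == 0).any() and not allow_missing:
                j = int(idx[np.argmax(overlap == 0)])
                raise NoOverlapError(
                    f"no overlap between {self.ids[i]!r} and {self.ids[j]!r}"
                )
            _, k2p = _vector_k2p(overlap, ts, tv)
            k2p = np.where(overlap > 0, k2p, np.nan)
            mat[i, i + 1 :] = k2p
            mat[i + 1 :, i] = k2p
        return mat


def _vector_k2p(overlap: np.ndarray, ts: np.ndarray, tv: np.ndarray):
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(overlap > 0, ts / np.maximum(overlap, 1), np.nan)
        Q = np.where(overlap > 0, tv / np.maximum(overlap, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        k2p = np.where(
            (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.maximum(w1, 1e-300))
            - 0.25 * np.log(np.maximum(w2, 1e-300)),
            np.inf,
        )
        similarity = 100.0 * (1.0 - (ts + tv) / np.maximum(overlap, 1))
        similarity = np.where(overlap > 0, similarity, np.nan)
    return similarity, k2p


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceMatrixResult:
    ids: list[str]
    matrix: np.ndarray  # square, symmetric, zero diagonal; inf = saturated

    def _off_diagonal(self) -> np.ndarray:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.matrix[iu]

    @property
    def mean(self) -> float:
        return float(np.mean(self._off_diagonal()))

    @property
    def min(self) -> float:
        return float(np.min(self._off_diagonal()))

    @property
    def max(self) -> float:
        return float(np.max(self._off_diagonal()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def distance_matrix(
    records: Sequence[SeqRecord], method: str = "pairwise", **aligner_kwargs
) -> DistanceMatrixResult:
    """Symmetric K2P matrix over a set of sequences.

    ``method='pairwise'`` aligns every pair exactly; ``method='anchor'``
    projects onto a common anchor first (identical on indel-free data, much
    faster for large sets).  Saturated cells hold ``inf``; a pair with no
    unambiguous overlap is an error naming the pair.
    """
    if len(records) < 2:
        raise ValueError("distance_matrix needs at least 2 records")
    ids = [r.id for r in records]
    if method == "anchor":
        panel = AnchorPanel(records, **aligner_kwargs)
        return DistanceMatrixResult(ids, panel.full_matrix())
    if method != "pairwise":
        raise ValueError(f"unknown method {method!r}")
    n = len(records)
    mat = np.zeros((n, n), dtype=np.float64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            comp = compare_records(records[i], records[j], **aligner_kwargs)
            mat[i, j] = mat[j, i] = comp.k2p
    return DistanceMatrixResult(ids, mat)
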