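"""Quality control of query amplicons before identification.

Three gates, all reported rather than raised: a minimum-length gate
(mini-barcodes down to 100 bp remain identifiable, shorter fragments are
rejected), an ambiguity gate, and a reading-frame check that flags
sequences whose best frame still contains an internal stop codon — on a
protein-coding mitochondrial marker a stop is the classic signature of a
nuclear pseudogene (numt) or a sequencing artefact.

The reading frame is chosen by stop minimisation over the three forward
frames rather than by alignment to a reference, because heavily divergent
("dark taxon") queries may have no close reference at all.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .io_formats import SeqRecord, UNAMBIGUOUS
from .synthetic_data import resolve_code_table

TOO_SHORT = "TOO_SHORT"
TOO_AMBIGUOUS = "TOO_AMBIGUOUS"
STOP_CODON = "STOP_CODON"


@dataclasses.dataclass(frozen=True)
class QCReport:
    id: str
    length: int
    ambiguous_fraction: float
    best_frame: int  # 1, 2 or 3
    stops_in_best_frame: int
    reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.reasons


def _count_stops(sequence: str, frame: int, stops: frozenset[str]) -> int:
    """Internal stop codons in one forward frame (1-based).

    The trailing partial codon is ignored; codons containing an ambiguous
    base are excluded from translation.
    """
    n = 0
    for start in range(frame - 1, len(sequence) - 2, 3):
        codon = sequence[start : start + 3]
        if set(codon) <= UNAMBIGUOUS and codon in stops:
            n += 1
    return n


def qc_sequence(
    record: SeqRecord,
    min_len: int = 100,
    max_ambiguous: float = 0.02,
    code_table: int | str = "vertebrate_mito",
) -> QCReport:
    """QC one sequence; all failures are report codes, never exceptions."""
    seq = record.sequence
    length = len(seq)
    ambiguous = sum(1 for b in seq if b not in UNAMBIGUOUS)
    ambiguous_fraction = ambiguous / length
    tid = resolve_code_table(code_table)
    stops = frozenset(CodonTable.unambiguous_dna_by_id[tid].stop_codons)
    stop_counts = [_count_stops(seq, frame, stops) for frame in (1, 2, 3)]
    best_frame = 1 + min(range(3), key=lambda i: stop_counts[i])
    reasons: list[str] = []
    if length < min_len:
        reasons.append(TOO_SHORT)
    if ambiguous_fraction > max_ambiguous:
        reasons.append(TOO_AMBIGUOUS)
    if stop_counts[best_frame - 1] > 0:
        reasons.append(STOP_CODON)
    return QCReport(
        id=record.id,
        length=length,
        ambiguous_fraction=ambiguous_fraction,
        best_frame=best_frame,
        stops_in_best_frame=stop_counts[best_frame - 1],
        reasons=tuple(reasons),
    )


@dataclasses.dataclass
class QCSummary:
    n_input: int
    n_passing: int
    per_reason: dict[str, int]


def qc_batch(
    records: Sequence[SeqRecord],
    min_len: int = 100,
    max_ambiguous: float = 0.02,
    code_table: int | str = "vertebrate_mito",
) -> tuple[list[SeqRecord], list[QCReport], QCSummary]:
    """Order-preserving partition into passing records plus all reports."""
    reports = [
        qc_sequence(r, min_len=min_len, max_ambiguous=max_ambiguous, code_table=code_table)
        for r in records
    ]
    passing = [r for r, rep in zip(records, reports) if rep.passed]
    per_reason: dict[str, int] = {}
    for rep in reports:
        for reason in rep.reasons:
            per_reason[reason] = per_reason.get(reason, 0) + 1
    summary = QCSummary(
        n_input=len(records), n_passing=len(passing), per_reason=per_reason
    )
    return passing, reports, summary


def reports_to_rows(reports: Iterable[QCReport]) -> list[dict]:
    return [
        {
            "id": rep.id,
            "length": rep.length,
            "ambiguous_fraction": f"{rep.ambiguous_fraction:.4f}",
            "best_frame": rep.best_frame,
            "stops_in_best_frame": rep.stops_in_best_frame,
            "pass": str(rep.passed).lower(),
            "reasons": ",".join(rep.reasons),
        }
        for rep in reports
    ]
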