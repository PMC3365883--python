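"""Readers/writers for the plain-text formats the pipeline touches.

FASTA (reference libraries and stomach-content amplicons), four-rank
tab-separated taxonomy tables, one-species-per-line regional checklists,
generic TSV result tables and newick trees.  The taxonomy convention is
deliberately minimal: exactly the four ranks the diet tables report
(order, family, genus, species), with partial resolution allowed from the
species end upward (a record identified only to genus simply leaves the
species cell empty).
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Ranks from coarsest to finest.
RANKS = ("order", "family", "genus", "species")

#: IUPAC nucleotide codes accepted in input sequences.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: Codes treated as unambiguous for distance computation.
UNAMBIGUOUS = set("ACGT")


@dataclasses.dataclass(frozen=True)
class TaxonPath:
    """Ranked taxonomy labels with partial resolution allowed.

    A non-empty label at any rank requires non-empty labels at all coarser
    ranks: a species without a genus is rejected.  Empty string means
    "unresolved at this rank".
    """

    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        labels = [self.order, self.family, self.genus, self.species]
        for label in labels:
            if "\t" in label or "\n" in label:
                raise ValueError(f"taxon label contains tab/newline: {label!r}")
        seen_empty = False
        for rank, label in zip(RANKS, labels):
            if label == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"rank {rank!r} is set but a coarser rank is empty: {labels}"
                )

    def label(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def resolution(self) -> str:
        """Finest non-empty rank, or '' for a fully empty path."""
        for rank in reversed(RANKS):
            if getattr(self, rank):
                return rank
        return ""

    def is_empty(self) -> bool:
        return self.resolution() == ""


@dataclasses.dataclass
class SeqRecord:
    """A barcode sequence plus its pipeline metadata.

    References carry a (possibly partial) :class:`TaxonPath`; queries carry
    the label of the predator whose stomach they came from.
    """

    id: str
    sequence: str
    role: str = "query"  # "reference" | "query"
    taxon: TaxonPath | None = None
    predator_label: str = ""
    locality: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if self.role not in ("reference", "query"):
            raise ValueError(f"bad role {self.role!r} for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, role: str = "query") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    Sequences are uppercased and U is mapped to T.  The description after
    the first whitespace of the header is stored as free-text locality.
    Duplicate ids and empty sequences are hard errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        free = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(
            SeqRecord(id=rec.id, sequence=str(rec.seq), role=role, locality=free)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.locality)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Taxonomy / checklist / generic tables
# ---------------------------------------------------------------------------

TAXONOMY_COLUMNS = ("id",) + RANKS


def read_taxonomy(path: str | os.PathLike) -> dict[str, TaxonPath]:
    """Read a TSV taxonomy table (id, order, family, genus, species).

    Empty cells denote unresolved ranks; a species with an empty genus
    violates the TaxonPath invariant and is an error.  Unknown columns are
    an error (they would silently be ignored otherwise).
    """
    result: dict[str, TaxonPath] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header) != TAXONOMY_COLUMNS:
            raise ValueError(
                f"taxonomy header must be {list(TAXONOMY_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(TAXONOMY_COLUMNS):
                cells += [""] * (len(TAXONOMY_COLUMNS) - len(cells))
            rec_id = cells[0].strip()
            if rec_id in result:
                raise ValueError(f"duplicate id {rec_id!r} at line {lineno}")
            try:
                result[rec_id] = TaxonPath(*(c.strip() for c in cells[1:5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return result


def write_taxonomy(taxa: Mapping[str, TaxonPath], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(TAXONOMY_COLUMNS) + "\n")
        for rec_id, taxon in taxa.items():
            handle.write(
                "\t".join(
                    [rec_id, taxon.order, taxon.family, taxon.genus, taxon.species]
                )
                + "\n"
            )


def read_checklist(path: str | os.PathLike) -> set[str]:
    """Read a regional species checklist: one binomial per line.

    Blank lines and '#' comments are ignored; duplicates collapse.
    """
    species: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                species.add(line)
    return species


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
) -> None:
    """Write dict-rows as a TSV with a header line."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _sanitise_label(label: str) -> str:
    return label.replace(" ", "_")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Serialise a tree as newick with branch lengths at full precision.

    Leaf labels have whitespace replaced by underscores; labels containing
    newick-reserved characters are single-quoted by dendropy.
    """
    if tree.seed_node is None or tree.seed_node.is_leaf() and len(tree.leaf_nodes()) < 2:
        raise ValueError("refusing to write an empty or single-leaf tree")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.taxon.label = _sanitise_label(leaf.taxon.label)
    tree.write(
        path=os.fspath(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=os.fspath(path), schema="newick", preserve_underscores=True
    )


def tree_from_newick_string(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        file=io.StringIO(text), schema="newick", preserve_underscores=True
    )
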