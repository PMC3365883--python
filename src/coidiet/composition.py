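"""Diet and sequence-composition analytics.

Percent composition by number (%N) tables with explicit denominator scopes,
taxon-richness counts, new-record flagging against a regional checklist,
cannibalism detection, and per-sequence base-composition statistics.

The denominator conventions follow how diet studies report these numbers:
class-level %N is taken over all prey sequences, fish family/species %N over
the fish sequences only, and crustacean order %N over the crustacean
sequences only — only this combination reproduces every percentage of the
motivating dataset simultaneously.

The package ships that dataset (the published prey roster of the invasive
lionfish *Pterois volitans* in the Mexican Caribbean: 125 fish and 43
crustacean prey sequences) as plain TSV under ``coidiet/data``; the loaders
at the bottom expose it for analyses and tests.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RANKS, SeqRecord, TaxonPath, UNAMBIGUOUS

#: Coarse class of each prey order seen in the study system.
ORDER_CLASS: dict[str, str] = {
    "Beryciformes": "fish",
    "Perciformes": "fish",
    "Pleuronectiformes": "fish",
    "Scorpaeniformes": "fish",
    "Tetraodontiformes": "fish",
    "Anguilliformes": "fish",
    "Decapoda": "crustacean",
    "Stomatopoda": "crustacean",
    "Euphausiacea": "crustacean",
}

SCOPES = ("all", "fish_only", "crustacean_only")


@dataclasses.dataclass(frozen=True)
class PreyRecord:
    """One identified prey sequence: an id plus its (possibly partial) taxon."""

    id: str
    taxon: TaxonPath


@dataclasses.dataclass(frozen=True)
class CompositionRow:
    rank: str
    taxon: str
    count: int
    percent_n: float  # full precision; round to 1 decimal for display
    denominator_scope: str


def _class_of(path: TaxonPath, order_class: Mapping[str, str]) -> str:
    return order_class.get(path.order, "other")


def _group_label(path: TaxonPath, rank: str) -> str:
    """Display label of a prey record at a rank.

    A record unresolved at the requested rank is labelled by its finest
    resolved label plus 'sp.' (e.g. a genus-only record appears as
    'Genus sp.' in the species table), mirroring how diet tables list
    partially identified prey.
    """
    label = path.label(rank)
    if label:
        return label
    for coarser in reversed(RANKS[: RANKS.index(rank)]):
        if path.label(coarser):
            return f"{path.label(coarser)} sp."
    return "unidentified"


def percent_n(
    prey: Sequence[PreyRecord],
    rank: str,
    scope: str = "all",
    order_class: Mapping[str, str] = ORDER_CLASS,
) -> list[CompositionRow]:
    """%N table at a rank ('class' or a taxonomy rank) under a scope.

    ``scope`` selects the denominator: every prey sequence, the fish
    sequences only, or the crustacean sequences only.  Percentages are kept
    at full precision and sum to 100 within rounding.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if rank != "class" and rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if scope == "fish_only":
        selected = [p for p in prey if _class_of(p.taxon, order_class) == "fish"]
    elif scope == "crustacean_only":
        selected = [p for p in prey if _class_of(p.taxon, order_class) == "crustacean"]
    else:
        selected = list(prey)
    denom = len(selected)
    counts: dict[str, int] = {}
    for p in selected:
        label = (
            _class_of(p.taxon, order_class)
            if rank == "class"
            else _group_label(p.taxon, rank)
        )
        counts[label] = counts.get(label, 0) + 1
    rows = [
        CompositionRow(
            rank=rank,
            taxon=label,
            count=c,
            percent_n=100.0 * c / denom,
            denominator_scope=scope,
        )
        for label, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.taxon))
    return rows


def composition_to_rows(rows: Sequence[CompositionRow]) -> list[dict]:
    return [
        {
            "rank": r.rank,
            "taxon": r.taxon,
            "count": r.count,
            "percent_n": f"{r.percent_n:.1f}",
            "denominator_scope": r.denominator_scope,
        }
        for r in rows
    ]


def richness(prey: Sequence[PreyRecord]) -> dict[str, int]:
    """Distinct taxa per rank.

    A genus-resolution record with no species label contributes one
    species-equivalent ('Genus sp.') beyond any named congeners, so a prey
    item identified only to genus still counts toward species richness.
    """
    distinct: dict[str, set[str]] = {rank: set() for rank in RANKS}
    for p in prey:
        for rank in RANKS:
            label = p.taxon.label(rank)
            if label:
                distinct[rank].add(label)
        if not p.taxon.species and p.taxon.genus:
            distinct["species"].add(f"{p.taxon.genus} sp.")
    return {rank: len(values) for rank, values in distinct.items()}


def flag_new_records(
    prey: Sequence[PreyRecord], checklist: Iterable[str]
) -> list[str]:
    """Species-rank identifications absent from the regional checklist,
    deduplicated and sorted.  Records not resolved to species never flag."""
    known = set(checklist)
    return sorted(
        {p.taxon.species for p in prey if p.taxon.species and p.taxon.species not in known}
    )


def flag_cannibalism(
    prey: Sequence[PreyRecord], predator_species: str
) -> tuple[int, list[str]]:
    """Prey sequences identified as the predator species itself."""
    if not predator_species:
        raise ValueError("predator species label must be non-empty")
    ids = [p.id for p in prey if p.taxon.species == predator_species]
    return len(ids), ids


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------

_STAT_ROWS = (
    "pct_g",
    "pct_c",
    "pct_a",
    "pct_t",
    "pct_gc",
    "pct_gc_pos1",
    "pct_gc_pos2",
    "pct_gc_pos3",
)


@dataclasses.dataclass
class BaseCompositionStats:
    per_sequence: pd.DataFrame  # one row per sequence, one column per stat
    aggregate: pd.DataFrame  # rows = stats, columns = min/mean/max/se


def _pct(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else float("nan")


def base_composition(records: Sequence[SeqRecord], frame: int = 1) -> BaseCompositionStats:
    """Per-sequence base percentages and GC by codon position.

    Ambiguous bases are excluded from every denominator, so G+C+A+T sums to
    100 per sequence.  Codon positions are indexed from ``frame`` (1-3); the
    records are expected to share one reading frame (from QC).
    SE is the sample standard deviation (n-1) over sqrt(n), 0 for n=1.
    """
    if not records:
        raise ValueError("no records")
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    rows = []
    for rec in records:
        seq = rec.sequence
        clear = [b for b in seq if b in UNAMBIGUOUS]
        denom = len(clear)
        counts = {b: clear.count(b) for b in "GCAT"}
        row = {
            "id": rec.id,
            "pct_g": _pct(counts["G"], denom),
            "pct_c": _pct(counts["C"], denom),
            "pct_a": _pct(counts["A"], denom),
            "pct_t": _pct(counts["T"], denom),
            "pct_gc": _pct(counts["G"] + counts["C"], denom),
        }
        for pos in (1, 2, 3):
            sub = [
                seq[i]
                for i in range(frame - 1 + pos - 1, len(seq), 3)
                if seq[i] in UNAMBIGUOUS
            ]
            gc = sum(1 for b in sub if b in "GC")
            row[f"pct_gc_pos{pos}"] = _pct(gc, len(sub))
        rows.append(row)
    per_seq = pd.DataFrame(rows).set_index("id")
    n = len(per_seq)
    agg = pd.DataFrame(
        {
            "min": per_seq.min(),
            "mean": per_seq.mean(),
            "max": per_seq.max(),
            "se": (per_seq.std(ddof=1) / np.sqrt(n)).fillna(0.0) if n > 1 else 0.0,
        },
        index=list(_STAT_ROWS),
    )
    return BaseCompositionStats(per_sequence=per_seq, aggregate=agg)


# ---------------------------------------------------------------------------
# Packaged study dataset
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("coidiet") / "data" / name


def load_fish_prey_table() -> pd.DataFrame:
    """Published fish prey roster (34 taxa, 125 sequences) with per-taxon
    sequence counts and best-match similarities."""
    with resources.as_file(_data_path("fish_prey_table.tsv")) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df


def load_crustacean_order_counts() -> pd.DataFrame:
    """Crustacean prey sequence counts by order (43 sequences)."""
    with resources.as_file(_data_path("crustacean_prey_orders.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_crustacean_match_table() -> pd.DataFrame:
    """Crustacean best-match similarities (79-100%), mostly partial taxa."""
    with resources.as_file(_data_path("crustacean_match_table.tsv")) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_regional_checklist() -> set[str]:
    from .io_formats import read_checklist

    with resources.as_file(_data_path("mexican_caribbean_checklist.txt")) as path:
        return read_checklist(path)


def study_prey_records() -> list[PreyRecord]:
    """Expand the packaged fish + crustacean tables into one PreyRecord per
    prey sequence (168 records)."""
    prey: list[PreyRecord] = []
    fish = load_fish_prey_table()
    for _, row in fish.iterrows():
        path = TaxonPath(
            order=row["order"],
            family=row["family"],
            genus=row["genus"],
            species=row["species"],
        )
        tag = (row["species"] or f"{row['genus']} sp").replace(" ", "_")
        for k in range(int(row["count"])):
            prey.append(PreyRecord(id=f"FISH_{tag}_{k + 1:02d}", taxon=path))
    crust = load_crustacean_order_counts()
    for _, row in crust.iterrows():
        path = TaxonPath(order=row["order"])
        for k in range(int(row["count"])):
            prey.append(PreyRecord(id=f"CRU_{row['order']}_{k + 1:02d}", taxon=path))
    return prey
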