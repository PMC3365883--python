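"""Synthetic COI reference libraries and degraded stomach-content queries.

The generator emulates the statistical structure a barcode-identification
pipeline relies on, so every downstream stage is testable without any
field-collected data:

* a balanced four-rank taxonomy (order/family/genus/species) laid out as an
  ultrametric guide tree whose depths separate the intraspecific and
  interspecific divergence bands;
* sequences evolved site-wise under the Kimura two-state (K80) substitution
  process — transitions occur at ``kappa`` times the rate of each
  transversion — using the exact transition probabilities, so the K2P
  estimator applied downstream is model-matched and divergence recovery is
  testable;
* protein-coding structure: the ancestor is built from non-stop codons and
  substitutions that would create an in-frame stop codon are redrawn,
  matching the empirical observation that real COI barcodes from stomach
  contents carry no indels or stop codons;
* queries as contiguous fragments of reference haplotypes with a configurable
  length mixture (the field mixture: 85% >=600 bp, a minority 300-500 bp,
  rare fragments <200 bp), plus extra substitution noise, "dark taxon"
  queries drawn from species withheld from the reference library, and
  cannibal queries drawn from the predator species itself.

Degradation is modelled as truncation plus substitutions only, never indels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import RANKS, SeqRecord, TaxonPath

CODE_TABLES = {"standard": 1, "vertebrate_mito": 2, "invertebrate_mito": 5}

_BASES = "ACGT"


def resolve_code_table(table: int | str) -> int:
    if isinstance(table, str):
        try:
            return CODE_TABLES[table]
        except KeyError:
            raise ValueError(f"unknown code table {table!r}") from None
    return int(table)


def stop_codons(table: int | str) -> frozenset[str]:
    """DNA stop codons of an NCBI translation table."""
    tid = resolve_code_table(table)
    return frozenset(CodonTable.unambiguous_dna_by_id[tid].stop_codons)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated community.

    Divergences are expected substitutions per site *between a pair*:
    ``intraspecific_div`` between two conspecific haplotypes,
    ``interspecific_div`` between two congeneric species, with
    ``deeper_div`` a per-rank multiplier for the genus/family/order splits.
    """

    seed: int = 0
    n_orders: int = 2
    families_per_order: int = 2
    genera_per_family: int = 3
    species_per_genus: int = 4
    haplotypes_per_species: int = 2
    barcode_length: int = 658
    kappa: float = 3.0
    intraspecific_div: float = 0.005
    interspecific_div: float = 0.10
    deeper_div: float = 1.5
    query_length_mix: tuple = ((0.85, 600, 658), (0.13, 300, 500), (0.02, 100, 199))
    query_error_rate: float = 0.005
    dark_taxon_fraction: float = 0.0
    cannibal_fraction: float = 0.0
    n_queries: int = 100
    code_table: int | str = "vertebrate_mito"
    predator_species: str | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_orders",
            "families_per_order",
            "genera_per_family",
            "species_per_genus",
            "haplotypes_per_species",
            "n_queries",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.barcode_length < 3:
            raise ValueError("barcode_length must be >= 3")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (self.intraspecific_div < self.interspecific_div):
            raise ValueError("intraspecific_div must be < interspecific_div")
        total = sum(p for p, _, _ in self.query_length_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("query_length_mix probabilities must sum to 1")
        for _, lo, hi in self.query_length_mix:
            if lo < 1 or hi < lo:
                raise ValueError("bad query length range")
            if lo > self.barcode_length:
                raise ValueError("requested fragment length exceeds barcode_length")
        for name in ("dark_taxon_fraction", "cannibal_fraction"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        resolve_code_table(self.code_table)


# ---------------------------------------------------------------------------
# K80 site process
# ---------------------------------------------------------------------------

def k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """Exact (transition, per-target transversion) probabilities after
    expected ``t`` substitutions/site under K80 with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def _evolve_codes(
    codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the K80 process on an encoded sequence (A0 C1 G2 T3).

    Transition partner is ``c ^ 2``; the two transversion targets are
    ``c ^ 1`` and ``c ^ 3``.
    """
    if t == 0.0:
        return codes.copy()
    p_ts, p_tv = k80_probs(t, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    out[u < p_ts] ^= 2
    m1 = (u >= p_ts) & (u < p_ts + p_tv)
    out[m1] ^= 1
    m2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[m2] ^= 3
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _codon_positions(length: int, frame_offset: int) -> range:
    """Start indices of complete codons given the 0-based frame offset."""
    return range(frame_offset, length - 2, 3)


def _repair_stops(
    child: np.ndarray,
    parent: np.ndarray,
    t: float,
    kappa: float,
    rng: np.random.Generator,
    stops: frozenset[str],
    frame_offset: int = 0,
    max_tries: int = 100,
) -> np.ndarray:
    """Redraw codons that became stops; fall back to the parent codon."""
    for start in _codon_positions(child.size, frame_offset):
        codon = _decode(child[start : start + 3])
        if codon not in stops:
            continue
        for _ in range(max_tries):
            redraw = _evolve_codes(parent[start : start + 3], t, kappa, rng)
            if _decode(redraw) not in stops:
                child[start : start + 3] = redraw
                break
        else:
            child[start : start + 3] = parent[start : start + 3]
    return child


def _evolve_coding(
    parent: np.ndarray,
    t: float,
    kappa: float,
    rng: np.random.Generator,
    stops: frozenset[str],
    frame_offset: int = 0,
) -> np.ndarray:
    child = _evolve_codes(parent, t, kappa, rng)
    return _repair_stops(child, parent, t, kappa, rng, stops, frame_offset)


def random_coding_ancestor(
    length: int, rng: np.random.Generator, stops: frozenset[str], max_tries: int = 1000
) -> np.ndarray:
    """Random in-frame coding sequence with no internal stop codons."""
    n_codons = (length + 2) // 3
    pool = [c for c in ("".join(p) for p in _all_codons()) if c not in stops]
    for _ in range(max_tries):
        idx = rng.integers(0, len(pool), size=n_codons)
        seq = "".join(pool[i] for i in idx)[:length]
        codes = np.array([_BASES.index(b) for b in seq], dtype=np.uint8)
        if not _has_stop(codes, stops):
            return codes
    raise RuntimeError("could not construct a stop-free ancestor")


def _all_codons():
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                yield a + b + c


def _has_stop(codes: np.ndarray, stops: frozenset[str], frame_offset: int = 0) -> bool:
    return any(
        _decode(codes[s : s + 3]) in stops
        for s in _codon_positions(codes.size, frame_offset)
    )


# ---------------------------------------------------------------------------
# Taxonomy and reference library
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimConfig) -> list[TaxonPath]:
    """Balanced taxonomy with globally unique labels, deterministic per config."""
    paths: list[TaxonPath] = []
    fam = gen = 0
    for o in range(1, config.n_orders + 1):
        for _ in range(config.families_per_order):
            fam += 1
            for _ in range(config.genera_per_family):
                gen += 1
                for s in range(1, config.species_per_genus + 1):
                    paths.append(
                        TaxonPath(
                            order=f"Ord{o}",
                            family=f"Fam{fam}",
                            genus=f"Gen{gen}",
                            species=f"Gen{gen} sp{s}",
                        )
                    )
    return paths


def simulate_reference_library(
    config: SimConfig, taxonomy: Sequence[TaxonPath]
) -> list[SeqRecord]:
    """Evolve one stop-free ancestor down the taxonomy guide tree.

    The guide tree is ultrametric: conspecific haplotypes coalesce at depth
    ``intraspecific_div/2``, congeneric species at ``interspecific_div/2``,
    and each coarser rank multiplies that depth by ``deeper_div``.  Expected
    pairwise divergence between two tips is twice their coalescence depth,
    i.e. exactly the configured band.
    """
    stops = stop_codons(config.code_table)
    rng = np.random.default_rng([config.seed, 0])
    h_hap = config.intraspecific_div / 2.0
    h_sp = config.interspecific_div / 2.0
    if h_hap >= h_sp:
        raise ValueError("intraspecific depth must be below species depth")
    h_gen = h_sp * config.deeper_div
    h_fam = h_gen * config.deeper_div
    h_ord = h_fam * config.deeper_div

    root = random_coding_ancestor(config.barcode_length, rng, stops)
    kappa = config.kappa

    def branch(parent: np.ndarray, depth_from: float, depth_to: float) -> np.ndarray:
        return _evolve_coding(parent, depth_from - depth_to, kappa, rng, stops)

    # Group species paths by order -> family -> genus, preserving input order.
    records: list[SeqRecord] = []
    by_order: dict[str, dict[str, dict[str, list[TaxonPath]]]] = {}
    for path in taxonomy:
        by_order.setdefault(path.order, {}).setdefault(path.family, {}).setdefault(
            path.genus, []
        ).append(path)

    for order_paths in by_order.values():
        order_seq = branch(root, h_ord, h_fam) if len(by_order) > 1 else root
        for family_paths in order_paths.values():
            fam_seq = branch(order_seq, h_fam, h_gen)
            for genus_paths in family_paths.values():
                gen_seq = branch(fam_seq, h_gen, h_sp)
                for path in genus_paths:
                    sp_seq = branch(gen_seq, h_sp, h_hap)
                    for h in range(1, config.haplotypes_per_species + 1):
                        tip = branch(sp_seq, h_hap, 0.0)
                        rec_id = path.species.replace(" ", "_") + f"_h{h}"
                        records.append(
                            SeqRecord(
                                id=rec_id,
                                sequence=_decode(tip),
                                role="reference",
                                taxon=path,
                            )
                        )
    return records


def split_library(
    library: Sequence[SeqRecord], withheld_species: Iterable[str]
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition a library into (public references, withheld dark pool)."""
    withheld = set(withheld_species)
    public = [r for r in library if r.taxon.species not in withheld]
    dark = [r for r in library if r.taxon.species in withheld]
    missing = withheld - {r.taxon.species for r in dark}
    if missing:
        raise ValueError(f"withheld species not in library: {sorted(missing)}")
    return public, dark


def choose_withheld_species(taxonomy: Sequence[TaxonPath], max_fraction: float = 0.25) -> list[str]:
    """Deterministic dark-taxon pool: the last species of every second genus
    that keeps at least one congener referenced."""
    by_genus: dict[str, list[str]] = {}
    for path in taxonomy:
        by_genus.setdefault(path.genus, []).append(path.species)
    eligible = [sp[-1] for g, sp in sorted(by_genus.items()) if len(sp) >= 2]
    chosen = eligible[::2]
    cap = max(1, int(round(max_fraction * len(taxonomy))))
    return chosen[:cap]


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def simulate_queries(
    config: SimConfig,
    library: Sequence[SeqRecord],
    withheld_species: Iterable[str] = (),
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw degraded query fragments plus a keyed truth sheet.

    Each query is a contiguous substring of a source haplotype (length from
    the configured mixture, uniform start) with additional substitutions at
    ``query_error_rate``, never creating a stop codon in the inherited
    reading frame.  ``dark_taxon_fraction`` of queries come from withheld
    species, ``cannibal_fraction`` from the predator species, the rest from
    the remaining referenced species.
    """
    rng = np.random.default_rng([config.seed, 1])
    stops = stop_codons(config.code_table)
    withheld = set(withheld_species)
    dark_pool = [r for r in library if r.taxon.species in withheld]
    if withheld and not dark_pool:
        raise ValueError("withheld species not present in the library")
    predator = config.predator_species or library[0].taxon.species
    cannibal_pool = [
        r for r in library if r.taxon.species == predator and r.taxon.species not in withheld
    ]
    normal_pool = [
        r
        for r in library
        if r.taxon.species not in withheld and r.taxon.species != predator
    ]
    if config.cannibal_fraction > 0 and not cannibal_pool:
        raise ValueError(f"predator species {predator!r} not in library")
    if config.dark_taxon_fraction > 0 and not dark_pool:
        raise ValueError("dark_taxon_fraction > 0 but no withheld species")
    if not normal_pool:
        raise ValueError("no non-dark, non-predator source haplotypes available")

    probs = np.array(
        [
            config.dark_taxon_fraction,
            config.cannibal_fraction,
            1.0 - config.dark_taxon_fraction - config.cannibal_fraction,
        ]
    )
    if probs[2] < -1e-9:
        raise ValueError("dark_taxon_fraction + cannibal_fraction must be <= 1")
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()

    mix_p = np.array([p for p, _, _ in config.query_length_mix])
    queries: list[SeqRecord] = []
    truth_rows: list[dict] = []
    for i in range(1, config.n_queries + 1):
        category = ("dark", "cannibal", "normal")[rng.choice(3, p=probs)]
        pool = {"dark": dark_pool, "cannibal": cannibal_pool, "normal": normal_pool}[
            category
        ]
        source = pool[rng.integers(0, len(pool))]
        comp = int(rng.choice(len(mix_p), p=mix_p))
        _, lo, hi = config.query_length_mix[comp]
        hi = min(hi, len(source.sequence))
        lo = min(lo, hi)
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(source.sequence) - length + 1))
        frag = np.array(
            [_BASES.index(b) for b in source.sequence[start : start + length]],
            dtype=np.uint8,
        )
        frame_offset = (3 - start % 3) % 3
        if config.query_error_rate > 0:
            child = _evolve_codes(frag, config.query_error_rate, config.kappa, rng)
            frag = _repair_stops(
                child,
                frag,
                config.query_error_rate,
                config.kappa,
                rng,
                stops,
                frame_offset,
            )
        qid = f"Q{i:04d}"
        queries.append(
            SeqRecord(
                id=qid,
                sequence=_decode(frag),
                role="query",
                predator_label=predator,
            )
        )
        truth_rows.append(
            {
                "query_id": qid,
                "source_id": source.id,
                "order": source.taxon.order,
                "family": source.taxon.family,
                "genus": source.taxon.genus,
                "species": source.taxon.species,
                "category": category,
                "length": length,
                "start": start,
            }
        )
    return queries, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Fixture:
    """One simulated study: references, queries, truth and the dark pool."""

    config: SimConfig
    taxonomy: list[TaxonPath]
    library: list[SeqRecord]  # full library incl. withheld species
    references: list[SeqRecord]  # public references only
    withheld_species: list[str]
    queries: list[SeqRecord]
    truth: pd.DataFrame

    @property
    def ref_taxonomy(self) -> dict[str, TaxonPath]:
        return {r.id: r.taxon for r in self.references}


def simulate_fixture(
    config: SimConfig, withheld_species: Sequence[str] | None = None
) -> Fixture:
    taxonomy = simulate_taxonomy(config)
    library = simulate_reference_library(config, taxonomy)
    if withheld_species is None:
        withheld_species = (
            choose_withheld_species(taxonomy) if config.dark_taxon_fraction > 0 else []
        )
    queries, truth = simulate_queries(config, library, withheld_species)
    references, _ = split_library(library, withheld_species)
    return Fixture(
        config=config,
        taxonomy=taxonomy,
        library=library,
        references=references,
        withheld_species=list(withheld_species),
        queries=queries,
        truth=truth,
    )


def write_fixture(fixture: Fixture, out_dir) -> dict[str, str]:
    """Write reference.fasta, reference_taxonomy.tsv, queries.fasta, truth.tsv."""
    import os

    from . import io_formats

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "reference": os.path.join(out_dir, "reference.fasta"),
        "taxonomy": os.path.join(out_dir, "reference_taxonomy.tsv"),
        "queries": os.path.join(out_dir, "queries.fasta"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    io_formats.write_fasta(fixture.references, paths["reference"])
    io_formats.write_taxonomy(fixture.ref_taxonomy, paths["taxonomy"])
    io_formats.write_fasta(fixture.queries, paths["queries"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
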