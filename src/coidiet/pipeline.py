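"""One reproducible run: QC -> identification -> diet composition.

A :class:`RunConfig` names the inputs (reference FASTA + taxonomy, query
FASTA, regional checklist, predator label) and parameters; `run_pipeline`
executes the stages, writes every table under the output directory and
records a manifest with input checksums, parameters, per-stage record
counts and the package version.  Record bookkeeping is conserved at every
stage: n_queries = n_pass_qc + n_fail_qc, and the assignments (including
method 'none') partition the QC-passing queries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from typing import Mapping

import yaml

from . import __version__, composition, identify, io_formats, seq_qc, synthetic_data

logger = logging.getLogger("coidiet")


@dataclasses.dataclass
class RunConfig:
    references: str
    taxonomy: str
    queries: str
    out_dir: str
    checklist: str = ""
    predator_species: str = ""
    min_len: int = 100
    max_ambiguous: float = 0.02
    code_table: str | int = "vertebrate_mito"
    species_threshold_pct: float = 3.0
    top_n: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("references", "taxonomy", "queries"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{name} path does not exist: {path!r}")
        if self.checklist and not os.path.exists(self.checklist):
            raise FileNotFoundError(f"checklist path does not exist: {self.checklist!r}")


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        references = io_formats.read_fasta(config.references, role="reference")
        taxonomy = io_formats.read_taxonomy(config.taxonomy)
        for ref in references:
            if ref.id not in taxonomy:
                raise ValueError(f"reference {ref.id!r} missing from taxonomy")
            ref.taxon = taxonomy[ref.id]
        queries = io_formats.read_fasta(config.queries, role="query")
        logger.info(
            "inputs: %d references, %d queries", len(references), len(queries)
        )

        passing, reports, qc_summary = seq_qc.qc_batch(
            queries,
            min_len=config.min_len,
            max_ambiguous=config.max_ambiguous,
            code_table=config.code_table,
        )
        io_formats.write_table(
            seq_qc.reports_to_rows(reports), os.path.join(config.out_dir, "qc.tsv")
        )
        logger.info(
            "qc: %d/%d passing (%s)",
            qc_summary.n_passing,
            qc_summary.n_input,
            qc_summary.per_reason,
        )

        assignments, report = identify.identify_batch(
            passing,
            references,
            taxonomy,
            species_threshold_pct=config.species_threshold_pct,
            top_n=config.top_n,
        )
        io_formats.write_table(
            identify.assignments_to_rows(assignments),
            os.path.join(config.out_dir, "assignments.tsv"),
        )
        logger.info("identify: %s by method, %s by rank", report.by_method, report.by_rank)

        prey = identify.prey_records(assignments, taxonomy)
        order_class = _infer_order_class(taxonomy)
        for rank, fname in (
            ("class", "composition_class.tsv"),
            ("family", "composition_family.tsv"),
            ("species", "composition_species.tsv"),
        ):
            scope = "all"
            rows = composition.percent_n(prey, rank, scope, order_class=order_class)
            io_formats.write_table(
                composition.composition_to_rows(rows),
                os.path.join(config.out_dir, fname),
            )
        rich = composition.richness(prey)
        io_formats.write_table(
            [{"rank": r, "distinct_taxa": n} for r, n in rich.items()],
            os.path.join(config.out_dir, "richness.tsv"),
        )
        new_records: list[str] = []
        if config.checklist:
            checklist = io_formats.read_checklist(config.checklist)
            new_records = composition.flag_new_records(prey, checklist)
        io_formats.write_table(
            [{"species": s} for s in new_records],
            os.path.join(config.out_dir, "new_records.tsv"),
            columns=["species"],
        )
        n_cannibal, cannibal_ids = (0, [])
        if config.predator_species:
            n_cannibal, cannibal_ids = composition.flag_cannibalism(
                prey, config.predator_species
            )
        io_formats.write_table(
            [{"query_id": i} for i in cannibal_ids],
            os.path.join(config.out_dir, "cannibalism.tsv"),
            columns=["query_id"],
        )
        # Base composition over the reference library (shared frame 1).
        basecomp = composition.base_composition(references, frame=1)
        basecomp.aggregate.round(4).to_csv(
            os.path.join(config.out_dir, "basecomp.tsv"), sep="\t"
        )

        manifest = {
            "tool": "coidiet",
            "version": __version__,
            "seed": config.seed,
            "parameters": dataclasses.asdict(config),
            "inputs": {
                name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
                for name in ("references", "taxonomy", "queries")
            },
            "counts": {
                "n_references": len(references),
                "n_queries": qc_summary.n_input,
                "n_pass_qc": qc_summary.n_passing,
                "n_fail_qc": qc_summary.n_input - qc_summary.n_passing,
                "qc_reasons": qc_summary.per_reason,
                "assignments_by_method": report.by_method,
                "assignments_by_rank": report.by_rank,
                "n_new_records": len(new_records),
                "n_cannibal": n_cannibal,
                "richness": rich,
            },
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        logger.info("done in %.1fs", time.time() - t0)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _infer_order_class(taxonomy: Mapping[str, io_formats.TaxonPath]) -> dict[str, str]:
    """Known orders keep their class; simulated/unknown orders count as fish."""
    mapping = dict(composition.ORDER_CLASS)
    for path in taxonomy.values():
        mapping.setdefault(path.order, "fish")
    return mapping


def make_demo_fixture(out_dir: str, seed: int = 0) -> dict[str, str]:
    """Small self-contained demo study: ~40 species x 2 haplotypes, 168
    queries with dark-taxon and cannibal components, plus a checklist and a
    ready-to-run YAML config."""
    config = synthetic_data.SimConfig(
        seed=seed,
        n_orders=2,
        families_per_order=2,
        genera_per_family=2,
        species_per_genus=5,
        haplotypes_per_species=2,
        n_queries=168,
        dark_taxon_fraction=0.15,
        cannibal_fraction=0.1,
    )
    fixture = synthetic_data.simulate_fixture(config)
    paths = synthetic_data.write_fixture(fixture, out_dir)
    # Checklist: all referenced species except the last of each family, so
    # the demo run surfaces "new records".
    by_family: dict[str, list[str]] = {}
    for path in fixture.taxonomy:
        if path.species not in fixture.withheld_species:
            by_family.setdefault(path.family, []).append(path.species)
    checklist = sorted(
        sp for family in by_family.values() for sp in family[:-1]
    )
    checklist_path = os.path.join(out_dir, "checklist.txt")
    with open(checklist_path, "w") as handle:
        handle.write("\n".join(checklist) + "\n")
    paths["checklist"] = checklist_path
    run_config = RunConfig(
        references=paths["reference"],
        taxonomy=paths["taxonomy"],
        queries=paths["queries"],
        out_dir=os.path.join(out_dir, "report"),
        checklist=checklist_path,
        predator_species=fixture.queries[0].predator_label if fixture.queries else "",
        seed=seed,
    )
    config_path = os.path.join(out_dir, "run.yaml")
    with open(config_path, "w") as handle:
        yaml.safe_dump(dataclasses.asdict(run_config), handle, sort_keys=False)
    paths["config"] = config_path
    return paths
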