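#!/usr/bin/env python
"""QC and identify the simulated stomach-content queries.

Reads the community written by 01_simulate_community.py, screens the
queries (length >= 100 bp, <= 2% ambiguity, no stop codon in the best
frame), assigns every survivor by the <3% K2P species rule with the
NJ strict-criterion fallback, and scores the calls against the truth
sheet.  Writes qc.tsv and assignments.tsv next to the inputs.
"""

import argparse
import os

import pandas as pd

from coidiet import identify, io_formats, seq_qc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--community-dir", default="results/community")
    parser.add_argument("--threshold", type=float, default=3.0)
    args = parser.parse_args()
    d = args.community_dir

    references = io_formats.read_fasta(os.path.join(d, "reference.fasta"), role="reference")
    taxonomy = io_formats.read_taxonomy(os.path.join(d, "reference_taxonomy.tsv"))
    for r in references:
        r.taxon = taxonomy[r.id]
    queries = io_formats.read_fasta(os.path.join(d, "queries.fasta"))
    truth = pd.read_csv(os.path.join(d, "truth.tsv"), sep="\t").set_index("query_id")

    passing, reports, summary = seq_qc.qc_batch(queries)
    io_formats.write_table(seq_qc.reports_to_rows(reports), os.path.join(d, "qc.tsv"))
    print(f"qc: {summary.n_passing}/{summary.n_input} passing "
          f"(failures by reason: {summary.per_reason or 'none'})")

    assignments, report = identify.identify_batch(
        passing, references, taxonomy, species_threshold_pct=args.threshold
    )
    io_formats.write_table(
        identify.assignments_to_rows(assignments), os.path.join(d, "assignments.tsv")
    )
    print(f"assignments by method: {report.by_method}; by rank: {report.by_rank}")

    amap = {a.query_id: a for a in assignments}
    nondark = truth[truth["category"] != "dark"]
    correct = sum(
        1 for qid, row in nondark.iterrows()
        if qid in amap and amap[qid].rank == "species" and amap[qid].taxon == row["species"]
    )
    print(f"non-dark queries recovered to true species: {correct}/{len(nondark)} "
          f"({100 * correct / len(nondark):.1f}%)")
    dark = truth[truth["category"] == "dark"]
    if len(dark):
        genus_ok = sum(
            1 for qid, row in dark.iterrows()
            if qid in amap and amap[qid].rank == "genus" and amap[qid].taxon == row["genus"]
        )
        at_species = sum(1 for qid in dark.index if qid in amap and amap[qid].rank == "species")
        print(f"dark taxa: {genus_ok}/{len(dark)} at correct genus, "
              f"{at_species} wrongly at species rank")


if __name__ == "__main__":
    main()
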