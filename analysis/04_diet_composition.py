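#!/usr/bin/env python
"""Diet composition of the invasive lionfish from the published prey roster.

Feeds the packaged per-taxon sequence counts (125 fish + 43 crustacean
prey sequences) through the composition module: %N by class, fish family
and fish species, crustacean orders, taxon richness, new regional records
against the prior checklist, and cannibalism.  Writes the tables under
results/diet/ and prints the headline numbers.
"""

import argparse
import os

from coidiet import composition as comp
from coidiet import io_formats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", default="results/diet")
    parser.add_argument("--predator", default="Pterois volitans")
    args = parser.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    study = comp.study_prey_records()
    fish = [p for p in study if comp.ORDER_CLASS.get(p.taxon.order) == "fish"]

    tables = {
        "composition_class.tsv": comp.percent_n(study, "class", "all"),
        "composition_fish_family.tsv": comp.percent_n(study, "family", "fish_only"),
        "composition_fish_species.tsv": comp.percent_n(study, "species", "fish_only"),
        "composition_crustacean_order.tsv": comp.percent_n(study, "order", "crustacean_only"),
    }
    for name, rows in tables.items():
        io_formats.write_table(
            comp.composition_to_rows(rows), os.path.join(args.out_dir, name)
        )

    class_rows = {r.taxon: r.percent_n for r in tables["composition_class.tsv"]}
    print(f"prey sequences: {len(study)} ({len(fish)} fish, {len(study) - len(fish)} crustacean)")
    print(f"%N by class: fish {class_rows['fish']:.1f}%, "
          f"crustaceans {class_rows['crustacean']:.1f}%")
    fam = {r.taxon: r.percent_n for r in tables["composition_fish_family.tsv"]}
    print("top fish families: " + ", ".join(
        f"{t} {fam[t]:.1f}%" for t in ("Labridae", "Gobiidae", "Scorpaenidae", "Scaridae")
    ))

    rich = comp.richness(fish)
    io_formats.write_table(
        [{"rank": r, "distinct_taxa": n} for r, n in rich.items()],
        os.path.join(args.out_dir, "richness.tsv"),
    )
    print(f"fish richness: {rich['order']} orders, {rich['family']} families, "
          f"{rich['genus']} genera, {rich['species']} species "
          f"(incl. one genus-only record counted as a species-equivalent)")

    new = comp.flag_new_records(study, comp.load_regional_checklist())
    io_formats.write_table(
        [{"species": s} for s in new],
        os.path.join(args.out_dir, "new_records.tsv"), columns=["species"],
    )
    print(f"new regional records: {len(new)} ({', '.join(new)})")

    n_cannibal, ids = comp.flag_cannibalism(study, args.predator)
    io_formats.write_table(
        [{"id": i} for i in ids],
        os.path.join(args.out_dir, "cannibalism.tsv"), columns=["id"],
    )
    print(f"prey sequences matching the predator itself ({args.predator}): {n_cannibal}")


if __name__ == "__main__":
    main()
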