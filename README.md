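# coidiet

Identification of predator and prey from COI DNA barcodes in stomach
contents, and the diet statistics built on those identifications.

Diet studies of invasive predators (the motivating case: the lionfish
*Pterois volitans* on Caribbean coral reefs) recover partially digested
tissue whose species cannot be determined morphologically. A short
mitochondrial COI fragment amplified from such tissue usually can be
identified by comparison against a barcode reference library. `coidiet`
implements that desk workflow end to end for ecologists analysing
stomach-content amplicons:

1. **QC** of degraded fragments: length gate (mini-barcodes ≥100 bp),
   ambiguity gate, and a reading-frame/stop-codon check that flags likely
   pseudogenes;
2. **distances**: semi-global alignment of each fragment against
   full-length references and the Kimura two-parameter distance over the
   aligned overlap, `d = -½ ln((1-2P-Q)√(1-2Q))` with `P`/`Q` the
   transition/transversion proportions (pairwise deletion of ambiguous
   sites);
3. **identification**: species assignment when the best match lies under
   the 3% K2P divergence rule and all in-band references agree; otherwise a
   neighbor-joining tree is built and the *strict criterion* applies — the
   unknown takes the taxon of the smallest enclosing clade whose reference
   members are unanimous at some rank (capped at genus, since a
   sub-threshold match cannot support a species call);
4. **composition**: percent composition by number (%N) with explicit
   denominator scopes, taxon richness, new-record flagging against a
   regional checklist, cannibalism detection, and base-composition
   statistics.

A synthetic-data module generates taxonomy-structured reference libraries
(K80 substitution process down an ultrametric guide tree, stop-codon-free
coding sequences) and degraded query fragments with a configurable length
mixture, dark taxa (species withheld from the references) and cannibal
queries — so the whole pipeline is testable without any field data. The
published prey tables of the lionfish study system (125 fish + 43
crustacean prey sequences, plus the prior regional checklist) ship as
packaged data for the composition analytics.

## Worked example

Simulate a community, identify its stomach-content queries, and score the
calls against the generator's truth sheet:

```bash
python analysis/01_simulate_community.py --out-dir results/community --seed 0
python analysis/02_qc_and_identify.py --community-dir results/community
```

```
community: 48 species, 84 reference haplotypes (6 species withheld as dark taxa)
queries: 168; >=600 bp: 85.7%, 300-500 bp: 13.1%, <200 bp: 1.2%
mean conspecific K2P: 0.418% (configured 0.500%)
mean congeneric K2P: 9.48% (configured 10.00%)
...
qc: 168/168 passing (failures by reason: none)
assignments by method: {'threshold': 146, 'strict-tree': 22}; by rank: {'species': 146, 'genus': 22}
non-dark queries recovered to true species: 146/146 (100.0%)
dark taxa: 22/22 at correct genus, 0 wrongly at species rank
```

146 queries matched a reference within the 3% rule and were called to
species — all correctly. The 22 queries drawn from the six withheld
("dark") species had no in-band match, fell through to the tree criterion,
and every one resolved to its true genus, never incorrectly to species.

The diet analytics on the packaged published roster:

```bash
python analysis/04_diet_composition.py --out-dir results/diet
```

```
prey sequences: 168 (125 fish, 43 crustacean)
%N by class: fish 74.4%, crustaceans 25.6%
top fish families: Labridae 26.4%, Gobiidae 20.0%, Scorpaenidae 12.8%, Scaridae 10.4%
fish richness: 5 orders, 14 families, 22 genera, 34 species (incl. one genus-only record counted as a species-equivalent)
new regional records: 7 (Apogon mosavi, Coryphopterus thrix, Coryphopterus tortugae, Coryphopterus venezuelae, Lythrypnus minimus, Starksia langi, Starksia ocellata)
prey sequences matching the predator itself (Pterois volitans): 16
```

Fish dominate the diet at 74.4% of prey sequences; seven prey species are
absent from the prior regional checklist (range extensions detected from
stomach contents), and 16 prey sequences match the predator species itself
— cannibalism.

The same stages are available as a CLI (`coidiet simulate|qc|distances|
tree|identify|compose|run|demo`); `coidiet demo --out-dir demo/` writes a
self-contained simulated study with a ready-to-run YAML config for
`coidiet run`.

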