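# Methods

`coidiet` re-creates, as a tested pipeline, the desk side of a DNA-barcoding
diet study: identifying partially digested prey from COI barcode fragments
recovered from predator stomachs, and summarising the identifications as
diet-composition statistics. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Identification model

**Distances.** Every comparison between a query fragment and a full-length
reference barcode is made over their aligned overlap. Percent similarity is
identity-based, `100 * (1 - p)` with `p` the proportion of mismatching
unambiguous sites; the species rule is applied to the Kimura two-parameter
distance

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

where `P` and `Q` are the transition (A<->G, C<->T) and transversion
proportions over the overlap. Sites with an ambiguity code or a gap in
either sequence are excluded pair by pair (pairwise deletion): queries are
fragments, and complete deletion would discard most of the signal. When
`1 - 2P - Q <= 0` or `1 - 2Q <= 0` the distance is reported as `+inf` and
flagged saturated rather than clamped, so downstream tree building is never
fed a silently truncated value.

**Alignment.** The reference primitive is an optimal semi-global (free
end-gap) affine alignment (match +1, mismatch -1, gap open -10, gap extend
-1), so a fragment aligns to its containing region at no cost. Internal gap
openings inside the overlap are counted and surfaced as a pseudogene/indel
diagnostic, not an automatic rejection — a COI barcode is expected to have
none. Batch stages (ranked hit search, distance matrices over hundreds of
sequences) would need ~10^5 pairwise alignments, so they instead align each
sequence once onto a common anchor (the longest sequence in the set) and
compute all pairwise counts over anchor coordinates, vectorised. On
indel-free sequences — the operative regime for mitochondrial COI — the
projection reproduces the exact pairwise alignment for every pair, and the
test suite asserts that equivalence; the exact aligner remains available as
`distance_matrix(..., method="pairwise")`.

**Threshold rule.** A query is identified to species when its best hit lies
below the species threshold (K2P x 100 < 3.0 by default) and every in-band
hit agrees at species rank. Disagreement within the band resolves to the
finest unanimous rank rather than nearest-neighbour-wins: with several
reference species inside the band, the nearest neighbour is not reliable
evidence. The assigned rank is additionally capped at the best reference's
own resolution — a genus-only reference can support at most a genus call.

**Strict tree criterion.** Queries with no in-band hit fall back to a
tree-based rule: build a neighbor-joining tree, root it, and assign the
taxon of the smallest enclosing clade whose reference members unanimously
carry one non-empty label at some rank, testing species first and
coarsening from there. Three choices here were open:

* *Rooting.* NJ trees are unrooted but "clade" needs a root. The tree is
  rooted at the midpoint of its longest reference-to-reference path;
  query leaves are excluded from the midpoint computation so an unknown on
  a long branch cannot drag the root toward itself.
* *One tree per query.* Each unresolved query is placed alone in a tree
  with the full reference library, rather than pooling all unresolved
  queries into one joint tree. Stomach contents typically contain many
  near-identical fragments of the same unreferenced prey species; in a
  joint tree those fragments form a query-only clade that can attach as a
  block to a single (possibly wrong) reference genus, and the assignment of
  every fragment then stands or falls together. Per-query trees keep
  unknowns perfectly independent, and they remove the need for
  query-to-query distances, which are undefined when two short fragments
  cover disjoint parts of the barcode.
* *Rank cap.* A best-hit divergence above the species threshold precludes a
  species-level identification by definition, so strict-tree assignments
  are capped at genus rank even when the query nests inside a single
  species' haplotype clade. (The `phylo.strict_criterion` primitive itself
  can return species rank; the cap is applied at the assignment layer.)

**Neighbor joining.** NJ is implemented directly so every choice is
bit-reproducible: the Q-criterion `Q(i,j) = (n-2) d(i,j) - r_i - r_j`,
branch lengths by the standard two-point formulas with negative estimates
clamped to zero, a trifurcating root, and all ties broken by the
lexicographically smallest pair of node labels (internal nodes inherit the
smallest leaf label beneath them). On additive matrices the implementation
recovers the generating topology and path lengths exactly (tested up to 12
taxa against four-point-condition enumeration, and cross-checked against an
independent NJ implementation).

## Sequence QC

Queries pass three gates before identification: minimum length (default
100 bp — mini-barcodes down to this length remain identifiable, shorter
fragments are rejected), maximum ambiguous-base fraction (default 2%, a
conservative barcode-community convention; the threshold is configurable
because no principled value exists), and a stop-codon check. The reading
frame is chosen by stop minimisation over the three forward frames rather
than by alignment to a reference, because dark-taxon queries may have no
close reference; a sequence whose best frame still contains a stop is
flagged as a likely pseudogene or artefact. Codons containing an ambiguous
base are excluded from translation, and the trailing partial codon is
ignored. Indel detection is deliberately delegated to the alignment stage
(gap openings inside the overlap), since an unaligned single sequence
cannot exhibit an indel.

## Synthetic communities

The generator produces the statistical structure the identification
procedure assumes, not a portrait of any particular fauna.

* **Taxonomy and guide tree.** A balanced order/family/genus/species
  hierarchy laid out as an ultrametric tree: conspecific haplotypes
  coalesce at depth `intraspecific_div / 2`, congeneric species at
  `interspecific_div / 2`, and each coarser rank multiplies the depth by
  `deeper_div`. Expected pairwise divergence between two tips is twice
  their coalescence depth, i.e. exactly the configured band.
* **Substitution process.** Sites evolve independently under the
  two-rate Kimura (K80) model with transition/transversion rate ratio
  `kappa`, using the exact finite-time transition probabilities. Matching
  the generating model to the K2P estimator makes divergence recovery a
  sharp test: the estimator is consistent under exactly this model.
* **Coding structure.** The ancestor is assembled from non-stop codons of
  the selected mitochondrial code (vertebrate by default, invertebrate
  selectable for crustacean-like fixtures) and substitutions that would
  create an in-frame stop are redrawn (reverting to the parent codon after
  100 failed draws). This reproduces the cleanliness expected of true
  mitochondrial barcodes, and gives the QC stage something real to check.
* **Queries.** Each query is a contiguous substring of a reference
  haplotype — length drawn from a configurable mixture, default 85%
  600-658 bp, 13% 300-500 bp, 2% 100-199 bp, matching the read-length
  profile reported for stomach-content amplicons — with extra substitutions
  at `query_error_rate` (degradation noise; no indels, which matches
  observation on real barcode data). A configurable fraction of queries
  comes from species withheld from the reference library (dark taxa) and
  from the predator species itself (cannibalism). A truth sheet records
  every query's source for recovery scoring.

Default parameters and why:

| parameter | default | rationale |
| --- | --- | --- |
| `barcode_length` | 658 | full COI barcode amplicon |
| `intraspecific_div` | 0.005 | typical within-species COI divergence (<1%) |
| `interspecific_div` | 0.10 | mean congeneric COI distance in fishes is ~10%; comfortably above the 3% rule |
| `deeper_div` | 1.5 | keeps family/order splits distinct without saturating K2P |
| `kappa` | 3.0 | transition bias typical of fish mtDNA |
| `query_error_rate` | 0.005 | degradation noise; no quantitative model exists for digested tissue, so this is a free parameter |
| `query_length_mix` | 85/13/2% | the field read-length mixture |

What the generator does **not** emulate: rate variation across sites and
codon positions, base-composition bias (the K80 stationary distribution is
uniform, so simulated GC content is ~50%, unlike the ~46% of real fish
COI), chimeras and contamination, alignment-relevant indels, and
realistically uneven taxon sampling. Consequently, passing recovery tests
show that the decision procedure is correct under its stated assumptions —
they do not bound its error rate on real stomach contents, where reference
incompleteness and PCR artefacts dominate.

## Diet composition

Percent composition by number (%N) is a count share with an explicit
denominator scope: class-level %N over all prey sequences, fish
family/species %N over fish sequences only, crustacean order %N over
crustacean sequences only. Only this combination of scopes reproduces
every published percentage of the motivating dataset simultaneously, and
each output row carries its scope so tables cannot be mixed silently.
Richness counts distinct taxa per rank, with a genus-resolution record and
no species label counted as one species-equivalent ("Genus sp.") — a prey
item identified only to genus is still a distinct species in the diet.
New-record flagging compares species-rank identifications against a
regional checklist; records not resolved to species never flag.
Base-composition statistics (per-sequence base percentages and GC by codon
position, with min/mean/max/SE aggregates; SE = sample SD / sqrt(n))
exclude ambiguous bases from every denominator.

The packaged study tables give the published per-taxon sequence counts
(125 fish across 34 taxa; 43 crustaceans across three orders) and the
26-binomial regional checklist. Two source quirks are normalised: the
fish table's "Malacoctenus triangulates" is spelled *M. triangulatus* (the
checklist spelling; the table form is an evident typo that would otherwise
create an eighth new record), and the crustacean order counts 40/2/1 are
reconstructed from the published order-level percentages, whose printed
one-decimal values (93/4.6/2.4) carry rounding inconsistencies relative to
any integer counts on n=43 (2/43 = 4.65%, 1/43 = 2.33%).

## Numerical and scale choices

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configurations produce
  byte-identical FASTA/TSV outputs.
* Ties are broken lexicographically everywhere (hit ranking, NJ joins,
  midpoint paths) for bit-reproducibility.
* Equality tolerances: NJ additivity checks at relative 1e-9; statistical
  recovery checks use 3 Monte-Carlo standard errors computed over
  independent replicates (per-species panels, since conspecific distances
  within one species share branches and are not independent).
* The recovery benchmark runs 1000 queries against a 48-species x 2
  haplotype library; the conspecific-divergence panels use 10 species x 30
  haplotypes. These sizes give sub-percent Monte-Carlo noise on the
  headline rates while keeping a full run in tens of seconds.

## Known limitations

* The anchor projection is exact only for indel-free data; sequences with
  real indels relative to the anchor lose the inserted bases from pairwise
  counts (the insertion count is surfaced on the panel object).
* The strict criterion inherits NJ's sensitivity to branch-length noise on
  very short fragments: a <200 bp dark-taxon fragment occasionally attaches
  one node outside its genus and resolves to family rank. This is visible
  in the benchmark (strict-genus accuracy ~97-100%, not 100%).
* `TaxonPath` fixes exactly four ranks (order, family, genus, species);
  intermediate ranks are out of scope.
* Identification quality is bounded by reference-library coverage; the
  pipeline can flag that a query is unreferenced (dark) but cannot name it.
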