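# Methods

`ctroeval` measures how reliably schema-based (template slot-filling)
annotations of clinical-trial abstracts can be produced, at two levels:
single entities (text spans labelled with ontology categories) and complex
entities (typed template instances whose slots hold entities, literals, or
references to other instances). This note records the statistical
procedures, the conventions chosen where more than one reading was
defensible, and what the synthetic test bed does and does not show.

## Annotation model

A schema (a YAML file; two are bundled) declares

* **entity categories** with a subsumption forest (`AngleClosureGlaucoma` →
  `Glaucoma` → `DisorderOrSyndrome`) and a *kind*: an ontology
  **individual** (a drug, a country) or a **literal** (a dose value, a free
  text description);
* **template types** (`Publication`, `ClinicalTrial`, `Population`, `Arm`,
  `Intervention`, `Medication`, `Endpoint`, `Outcome`,
  `DiffBetweenGroups`), each with typed slots. A slot's filler kind is
  `entity`, `literal`, or `template` (a cross-reference); `functional`
  slots admit at most one fill. Functional flags are configuration, not
  claims about the source ontology: where a cardinality is not known the
  slot defaults to non-functional.

Spans are 0-based, half-open token intervals everywhere. Overlapping and
embedded entity spans are first-class: the CoNLL-style dialect carries
`Category[ann_id]` tags (pipe-joined when stacked) rather than BIO
prefixes, because BIO cannot express two `Drug` mentions embedded in a
wider `Drug` annotation of a fixed combination. An entity is the maximal
run of consecutive lines sharing its id, so the format round-trips
losslessly.

Template annotations serialize to N-Triples: one `rdf:type` statement per
instance plus one statement per fill; individual-kind entity fills become
IRIs in the data namespace, literal-kind ones plain quoted literals. The
triple count therefore always equals instance count + fill count, which
the tests use as a conservation oracle. Reading RDF back cannot recover
token spans, so entity fills return as value-bearing fills (an individual
name or a literal); when a referenced instance carries no type statement
its type is inferred from the referencing slot if that slot admits exactly
one type.

## Token-level agreement (Cohen's kappa)

For each *general* category g (every category is mapped to its configured
group, defaulting to its topmost ancestor) each annotator induces a binary
marking of tokens: marked iff covered by some entity whose group is g
(union over overlapping spans). Kappa is

    kappa = (P(A) - P(E)) / (1 - P(E))

with P(A) the observed token-level agreement and P(E) the chance agreement
from the marginal marking rates. Conventions:

* Tokens are **pooled corpus-wide** per category before tabulation, not
  averaged per document: the statistic is one value per category per
  corpus, and pooling is the simplest reading consistent with that. This
  is a choice; per-document averaging would weight short documents up.
* The corpus **average is the unweighted mean** over categories annotated
  by at least one annotator; categories untouched by both are reported as
  absent, not zero. Frequency weighting is deliberately not applied.
* When P(E) = 1 (both marginals degenerate) kappa is undefined; it is
  reported as 1 if the markings are identical, else 0, with an
  `undefined` flag, so batch reports never crash on degenerate corners.
* Agreement bands: < 0 none, ≤ 0.20 slight, ≤ 0.40 fair, ≤ 0.60 moderate,
  ≤ 0.80 substantial, ≤ 1 almost perfect. Treating each printed upper
  bound as inclusive gives a total rule; a value such as 0.205 falls in
  the band of its next printed bound (fair).

The implementation is cross-checked in the test suite against
scikit-learn's `cohen_kappa_score` on randomly generated 2×2 tables.

## Complex-entity agreement (alignment-based micro-F1)

Annotators need not agree on how many instances of a template type exist,
so slot bookkeeping requires an instance alignment first. With
F1 = 2·tp / (fp + fn + 2·tp):

1. For every cross pair of same-type instances, a pair score is computed
   over **single-entity slots only**: per slot, fills are matched one-to-one
   on equal values (individuals by name, literals whitespace-normalized;
   token positions are ignored — any mention of the right entity fills a
   slot correctly). Matched fills are tp, surplus on the compared side fp,
   surplus on the reference side fn; the pair score is the F1 of the sums.
2. **Greedy best-first alignment**: repeatedly align the remaining pair
   with the highest score; ties break on the lexicographically smallest
   (id_A, id_B). The iterative "take the best pair" description reads
   greedy, and a total deterministic order is required for
   reproducibility. A globally optimal assignment (maximizing total tp,
   score as tie-break, via `scipy.optimize.linear_sum_assignment`) is
   available as `method="optimal"` and as a test oracle; on lists up to
   3×3 the greedy result is additionally checked against exhaustive
   enumeration.
3. Pairs scoring 0 are never aligned — an all-wrong pairing is
   indistinguishable from no pairing and would corrupt step 4. One corner
   is special: a pair in which *neither* instance carries any
   single-entity fill agrees vacuously and scores 1, so purely
   cross-referencing instances (an `Intervention` whose only fill is
   `hasMedication`) can still be aligned; without this, an annotation set
   compared against its own copy would not score 1.
4. Slot fills of aligned pairs contribute their tp/fp/fn; every fill of an
   unaligned instance counts wholly against its side. A cross-referencing
   fill is a tp iff the two referenced instances were themselves aligned
   (one-to-one within the slot), else fp/fn by side.
5. The **overall agreement is the micro-averaged F1**: counts summed over
   all slot types before applying the formula, weighting every fill
   equally — appropriate because fills are very unevenly distributed over
   slot types. Ordered cross-reference slots (`hasOutcome1`/`hasOutcome2`)
   are distinct slot names and hence compared in order.

Role symmetry: swapping the compared and reference sides swaps fp and fn
per slot and preserves every F1 (checked as a property test; alignment
tie-breaks can in principle differ under swap only between pairs of equal
score, which leaves the totals unchanged).

## Span-level NER evaluation

* **Exact match**: a prediction is a tp iff an unconsumed gold entity of
  identical type, start and end exists; consumption is one-to-one.
* **Partial match**: predictions are processed in document order (start,
  end, then type name — the order had to be fixed somewhere and document
  order is the natural reading); each consumes the first unconsumed gold
  entity of the same type sharing ≥ 1 token. Partial matching is **typed**:
  per-type score tables only make sense if a match requires type identity.
  An untyped variant can be had by relabelling, but is not the default.
* Precision with zero predictions (and recall with zero gold) is reported
  as 0 with an `undefined` flag rather than omitted, matching how such
  rows are conventionally printed.
* `min_count_filter` restricts evaluation to entity types with at least a
  threshold number of training occurrences (default 20, inclusive).

Micro averages always recompute from the summed per-type counts.

## Synthetic two-annotator corpus

The generator emulates the shape the scorers consume, over the bundled
mini schema: per document ~120–200 tokens of synthetic vocabulary, entity
spans placed by per-category Bernoulli rates per token (defaults roughly
0.4–1.5 % per category, giving ~30 entities per document), 8 % of entities
accompanied by an overlapping/embedded same-category twin, and one trial
structure per document (Publication → ClinicalTrial → two Arms, each with
Intervention → Medication and Outcome → shared Endpoint, plus Population
and DiffBetweenGroups); optional slots fill with probability 0.9. One
integer seed drives per-document sub-streams (`numpy.random.SeedSequence`
spawning), so corpora are reproducible and extendable.

The second annotator is derived by independent per-item perturbations,
each modelled on an observed human disagreement cause, all rates default
0: `p_drop_entity` (missed annotation; fills referencing it vanish too),
`p_type_swap` (category confusion within the same kind), boundary jitter
(`p_boundary_shift` with configurable offsets, optionally restricted to
textual categories — numeric entities disagree less in practice),
`p_drop_template`, `p_drop_slot` (missed fills), `p_swap_filler` (wrong
filler choice). Every change is logged; `recover_rates` re-estimates the
drop and confusion rates from span-matched confusion counts, converging at
binomial rate (±0.03 needs ≳ 2000 entities, i.e. ~75 documents).

What the synthetic bed does **not** emulate: real token distributions,
semantics, annotator-specific biases, correlated disagreements (a
confused guideline affecting all documents at once), or curation. Passing
tests show the statistics are computed correctly and respond to controlled
disagreement as derived in closed form — not that any particular real
corpus will reach a given agreement level.

## Problem sizes and runtime

The test suite and the reproduction script run at desk scale: 4–20
documents for scorer checks, 75 documents (~2200 entities) for rate
recovery, 100 documents for round-trip checks, 500 random instance-list
pairs (≤ 3×3) for alignment-oracle equivalence, and a 10 000-token
simulation for the chance-agreement null. The full suite completes in a
few seconds on one CPU.

## Known limitations

* The greedy aligner is order-dependent under score ties; the optimal
  matcher is provided where exactness matters.
* Agreement on complex entities is not chance-corrected; micro-F1 is the
  reported statistic.
* The N-Triples reader keys on IRI local names, so two namespaces
  differing only in base are conflated by design (the bases are
  configuration).
* Literal comparison is exact after whitespace normalization; "0.5" and
  "0.50" do not match.
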