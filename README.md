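# ctroeval

A toolkit for **schema-based (template slot-filling) annotation of
clinical-trial abstracts**: reading and writing the standard
serializations, validating annotations against an ontology-shaped schema,
and computing the agreement and evaluation statistics used to assess such
corpora.

Fine-grained clinical-trial corpora annotate randomized-controlled-trial
abstracts at two levels. *Single entities* are text spans labelled with a
category from an ontology — either an individual (a drug such as
`Bimatoprost`, a condition such as `Glaucoma`) or a literal value (a dose
value, a time point). *Complex entities* are template instances (`Arm`,
`Intervention`, `Medication`, `Outcome`, ...) whose typed slots are filled
with entities, literals, or references to other templates — the structure
needed to populate a knowledge base and aggregate evidence across trials.
Entity annotations travel as CoNLL-style one-token-per-line files (with
id-carrying tags, so overlapping and embedded spans survive); template
annotations travel as W3C N-Triples following a C-TrO-shaped schema.

The toolkit computes three families of statistics:

* **Token-level inter-annotator agreement** — per-category Cohen's kappa,
  `κ = (P(A) − P(E)) / (1 − P(E))`, over token markings pooled
  corpus-wide, with categories grouped to their most general ancestor and
  the usual agreement bands (0.61–0.80 substantial, 0.81–1 almost
  perfect, ...).
* **Complex-entity agreement** — a best pairwise alignment of template
  instances by the F1 of their single-entity slot fills
  (`F1 = 2tp / (fp + fn + 2tp)`), tp/fp/fn bookkeeping per slot
  (cross-references count as tp iff their referents are aligned), and an
  overall **micro-averaged F1** over all slot types.
* **NER span evaluation** — precision/recall/F1 per entity type with
  exact or partial (≥ 1 shared token, one-to-one consumption) matching,
  micro averages, and an occurrence-count training filter.

A synthetic two-annotator corpus generator with controlled, logged
disagreement rates (missed entities, type confusion, boundary jitter,
dropped templates/slots, filler swaps) makes every statistic testable
without any external data, including closed-form parameter recovery.

## Worked example

Generate a 10-document synthetic corpus, derive a disagreeing second
annotator (10 % missed entities, 5 % category confusions, 10 % missed
slot fills), and score it:

```python
import ctroeval as ce

schema = ce.load_schema("mini")
config = ce.GeneratorConfig(
    seed=42, n_docs=10,
    perturbation=ce.PerturbationConfig(
        p_drop_entity=0.1, p_type_swap=0.05, p_drop_slot=0.1),
)
golds = ce.generate_gold(config, schema)
pairs = ce.perturb_corpus(golds, config, schema)
others = [p.other for p in pairs]

kappa = ce.kappa_report(others, golds, schema)
templates = ce.score_corpus(others, golds, schema)
exact = ce.evaluate_documents(others, golds, mode="exact")
partial = ce.evaluate_documents(others, golds, mode="partial")
est = ce.recover_rates(pairs)

drug = kappa.result("Drug")
c = templates.per_slot[("Medication", "hasDrug")]
print(f"categories scored: {len(kappa.per_category)}")
print(f"average kappa:     {kappa.average:.3f} ({ce.classify_kappa(kappa.average)})")
print(f"Drug kappa:        {drug.kappa:.3f}  (P(A)={drug.p_a:.3f}, P(E)={drug.p_e:.3f})")
print(f"template micro-F1: {templates.micro_f1:.3f}")
print(f"hasDrug:           tp={c.tp} fp={c.fp} fn={c.fn}  F1={ce.f1(c):.3f}")
print(f"NER micro-F1:      exact {exact.micro.f1:.3f}, partial {partial.micro.f1:.3f}")
print(f"recovered rates:   drop {est.p_drop_entity:.3f} (true 0.10), "
      f"confusion {est.p_type_swap:.3f} (true 0.05)")
```

which prints:

```text
categories scored: 16
average kappa:     0.912 (almost perfect)
Drug kappa:        0.930  (P(A)=0.992, P(E)=0.889)
template micro-F1: 0.810
hasDrug:           tp=17 fp=0 fn=1  F1=0.971
NER micro-F1:      exact 0.913, partial 0.913
recovered rates:   drop 0.088 (true 0.10), confusion 0.046 (true 0.05)
```

Reading the numbers: dropping a tenth of the entities costs roughly a
tenth of the token marks per category, so kappa stays high but falls from
1; dropped entities also empty template slots, which (together with the
dropped fills) pulls the slot-level micro-F1 to 0.81; and the recovered
perturbation rates land within binomial error of the rates that generated
the disagreement. `ce.examples.bimatoprost_arm()` holds a small worked
structure — an interventional arm with medication bimatoprost 0.03 %
once daily — whose RDF export is exactly the eight statements shown in
`ctroeval/examples.py`.

The same pipelines run from the shell:

```bash
ctroeval synth --seed 42 --n-docs 10 --p-drop-entity 0.1 --out corpus/
ctroeval kappa --gold corpus/annotator1.conll --other corpus/annotator2.conll --out reports/
ctroeval template-f1 --gold corpus/annotator1 --other corpus/annotator2 --out reports/
ctroeval ner-eval --gold corpus/annotator1.conll --pred corpus/annotator2.conll --mode partial --out reports/
ctroeval validate --conll corpus/annotator1.conll --nt corpus/annotator1
ctroeval corpus-stats --conll corpus/annotator1.conll --nt corpus/annotator1
```

Reports are TSV plus a machine-readable JSON twin; logs go to stderr.

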