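"""Agreement on complex entities: instance alignment and micro-averaged F1.

Two annotators of the same abstract need not agree on how many instances of
a template type exist (one may see two Medication templates where the other
sees one), so slot-level bookkeeping first requires an alignment between the
instance lists.  Candidate pairs are scored by the F1 of their single-entity
slot fills — F1 = 2tp / (fp + fn + 2tp) — and the pair with the highest F1
is aligned first (greedy best-first, deterministic tie-breaks); a globally
optimal assignment is available as an opt-in alternative.  Slot fills of
aligned pairs contribute tp/fp/fn per slot; every fill of an unaligned
instance counts against its own side.  A cross-referencing (complex-entity)
slot fill is a true positive iff the two referenced instances were
themselves aligned.  Token positions never matter: two annotators choosing
different mentions of the same drug for ``hasDrug`` agree.

The overall agreement is the micro-averaged F1: tp/fp/fn summed over all
slot types before applying the F1 formula, weighting each fill equally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal as TLiteral
from typing import Optional, Sequence, Union

from scipy.optimize import linear_sum_assignment

from .model import AnnotationSet, Filler, TemplateFill, TemplateInstance
from .rdf_io import normalize_literal
from .schema import SchemaDef


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("negative match count")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn

    def swapped(self) -> "MatchCounts":
        return MatchCounts(self.tp, self.fn, self.fp)


def f1(counts: MatchCounts) -> float:
    """F1 = 2tp / (fp + fn + 2tp); undefined on all-zero counts."""
    if counts.total == 0:
        raise ValueError("F1 undefined on all-zero counts")
    return 2 * counts.tp / (counts.fp + counts.fn + 2 * counts.tp)


def _f1_or_none(counts: MatchCounts) -> Optional[float]:
    return None if counts.total == 0 else f1(counts)


# -- fill comparison ---------------------------------------------------------


def fill_value(
    fill: Filler, context: AnnotationSet, schema: SchemaDef
) -> Optional[tuple[str, str]]:
    """Comparable (kind, value) of a single-entity fill; None for templates.

    Individual-kind entity fills compare by individual/category name,
    literal-kind ones by their whitespace-normalized surface string.
    """
    from .model import EntityFill, IndividualFill, LiteralFill

    if isinstance(fill, TemplateFill):
        return None
    if isinstance(fill, LiteralFill):
        return ("literal", normalize_literal(fill.value))
    if isinstance(fill, IndividualFill):
        return ("individual", fill.name)
    if isinstance(fill, EntityFill):
        ent = context.entity(fill.ann_id)
        cat = schema.categories.get(ent.category)
        if cat is not None and cat.kind == "literal":
            return ("literal", normalize_literal(ent.surface))
        return ("individual", ent.category)
    raise TypeError(f"unrecognised fill {fill!r}")


def fill_match(
    fill_a: Filler,
    fill_b: Filler,
    context_a: AnnotationSet,
    context_b: AnnotationSet,
    schema: SchemaDef,
) -> bool:
    """True iff two single-entity fills agree in kind and value."""
    va = fill_value(fill_a, context_a, schema)
    vb = fill_value(fill_b, context_b, schema)
    if va is None or vb is None:
        return False
    return va == vb


def _single_entity_values(
    inst: TemplateInstance, context: AnnotationSet, schema: SchemaDef
) -> dict[str, list[tuple[str, str]]]:
    """Per-slot multisets of comparable values over single-entity fills."""
    out: dict[str, list[tuple[str, str]]] = {}
    for slot, fill in inst.fills:
        value = fill_value(fill, context, schema)
        if value is not None:
            out.setdefault(slot, []).append(value)
    return out


def _multiset_match(
    values_a: list, values_b: list
) -> tuple[int, int, int]:
    """Maximum one-to-one matching of equal values: (tp, fp, fn)."""
    remaining = list(values_b)
    tp = 0
    for v in values_a:
        if v in remaining:
            remaining.remove(v)
            tp += 1
    return tp, len(values_a) - tp, len(remaining)


def pair_slot_counts(
    inst_a: TemplateInstance,
    inst_b: TemplateInstance,
    context_a: AnnotationSet,
    context_b: AnnotationSet,
    schema: SchemaDef,
) -> dict[str, MatchCounts]:
    """tp/fp/fn per single-entity slot for one candidate instance pair.

    B is the reference side: its unmatched fills are false negatives.
    """
    if inst_a.template_type != inst_b.template_type:
        raise AlignmentError(
            f"cannot compare {inst_a.template_type} with {inst_b.template_type}"
        )
    vals_a = _single_entity_values(inst_a, context_a, schema)
    vals_b = _single_entity_values(inst_b, context_b, schema)
    counts: dict[str, MatchCounts] = {}
    for slot in sorted(set(vals_a) | set(vals_b)):
        tp, fp, fn = _multiset_match(vals_a.get(slot, []), vals_b.get(slot, []))
        counts[slot] = MatchCounts(tp, fp, fn)
    return counts


def pair_counts(
    inst_a: TemplateInstance,
    inst_b: TemplateInstance,
    context_a: AnnotationSet,
    context_b: AnnotationSet,
    schema: SchemaDef,
) -> MatchCounts:
    total = MatchCounts()
    for c in pair_slot_counts(inst_a, inst_b, context_a, context_b, schema).values():
        total = total + c
    return total


def pair_f1(
    inst_a: TemplateInstance,
    inst_b: TemplateInstance,
    context_a: AnnotationSet,
    context_b: AnnotationSet,
    schema: SchemaDef,
) -> float:
    """Single-entity-slot F1 of a candidate pair; 0 when neither has fills."""
    counts = pair_counts(inst_a, inst_b, context_a, context_b, schema)
    value = _f1_or_none(counts)
    return 0.0 if value is None else value


# -- alignment ---------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    pairs: tuple[tuple[str, str, float], ...]  # (inst_id_A, inst_id_B, pair F1)
    unaligned_a: tuple[str, ...]
    unaligned_b: tuple[str, ...]

    def aligned_ids(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}


AlignmentMethod = TLiteral["greedy", "optimal"]


def align_instances(
    list_a: Sequence[TemplateInstance],
    list_b: Sequence[TemplateInstance],
    context_a: AnnotationSet,
    context_b: AnnotationSet,
    schema: SchemaDef,
    method: AlignmentMethod = "greedy",
) -> AlignmentResult:
    """Best pairwise alignment of two instance lists of one template type.

    ``greedy`` repeatedly aligns the remaining cross pair with the highest
    pair F1 (ties broken by the lexicographically smallest id pair);
    ``optimal`` solves the assignment maximizing total matched fills (tp),
    with total F1 as tie-break.  Pairs with F1 = 0 are never formed: an
    all-wrong pairing carries no more information than no pairing and would
    corrupt the tp-iff-aligned rule for cross-referencing slots.  A pair in
    which *neither* instance carries any single-entity fill agrees
    vacuously and scores 1, so purely cross-referencing instances can still
    be aligned.
    """
    types = {t.template_type for t in itertools.chain(list_a, list_b)}
    if len(types) > 1:
        raise AlignmentError(f"mixed template types {sorted(types)}")
    scores: dict[tuple[str, str], tuple[float, int]] = {}
    for a in list_a:
        for b in list_b:
            counts = pair_counts(a, b, context_a, context_b, schema)
            value = _f1_or_none(counts)
            scores[(a.inst_id, b.inst_id)] = (
                1.0 if value is None else value,  # empty-vs-empty: vacuous
                counts.tp,
            )

    pairs: list[tuple[str, str, float]] = []
    if method == "greedy":
        free_a = [a.inst_id for a in list_a]
        free_b = [b.inst_id for b in list_b]
        while free_a and free_b:
            # maximal F1 first, then the lexicographically smallest id pair
            best_f1 = max(scores[(a, b)][0] for a in free_a for b in free_b)
            if best_f1 <= 0.0:
                break
            best = min(
                (a, b)
                for a in free_a
                for b in free_b
                if scores[(a, b)][0] == best_f1
            )
            pairs.append((best[0], best[1], best_f1))
            free_a.remove(best[0])
            free_b.remove(best[1])
    elif method == "optimal":
        if list_a and list_b:
            # weight = tp + eps * F1: maximizes total tp, F1 as tie-break
            eps = 1e-6
            ids_a = [a.inst_id for a in list_a]
            ids_b = [b.inst_id for b in list_b]
            cost = [
                [
                    -(scores[(a, b)][1] + eps * scores[(a, b)][0])
                    for b in ids_b
                ]
                for a in ids_a
            ]
            rows, cols = linear_sum_assignment(cost)
            for i, j in sorted(zip(rows, cols)):
                a, b = ids_a[i], ids_b[j]
                if scores[(a, b)][0] > 0.0:
                    pairs.append((a, b, scores[(a, b)][0]))
        free_a = [a.inst_id for a in list_a if a.inst_id not in {p[0] for p in pairs}]
        free_b = [b.inst_id for b in list_b if b.inst_id not in {p[1] for p in pairs}]
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    return AlignmentResult(
        pairs=tuple(pairs),
        unaligned_a=tuple(free_a),
        unaligned_b=tuple(free_b),
    )


# -- corpus-level bookkeeping ------------------------------------------------


@dataclass
class SlotAgreementReport:
    """Per-slot match counts and F1, plus the overall micro-average."""

    per_slot: dict[tuple[str, str], MatchCounts] = field(default_factory=dict)

    def add(self, template_type: str, slot: str, counts: MatchCounts) -> None:
        key = (template_type, slot)
        self.per_slot[key] = self.per_slot.get(key, MatchCounts()) + counts

    def merge(self, other: "SlotAgreementReport") -> "SlotAgreementReport":
        merged = SlotAgreementReport(per_slot=dict(self.per_slot))
        for (tt, slot), counts in other.per_slot.items():
            merged.add(tt, slot, counts)
        return merged

    def slot_f1(self, template_type: str, slot: str) -> Optional[float]:
        return _f1_or_none(self.per_slot[(template_type, slot)])

    @property
    def summed(self) -> MatchCounts:
        total = MatchCounts()
        for counts in self.per_slot.values():
            total = total + counts
        return total

    @property
    def micro_f1(self) -> float:
        return f1(self.summed)


def score_annotation_sets(
    set_a: AnnotationSet,
    gold: AnnotationSet,
    schema: SchemaDef,
    method: AlignmentMethod = "greedy",
) -> SlotAgreementReport:
    """Template-level agreement of one annotator against a reference set."""
    if set_a.document.doc_id != gold.document.doc_id:
        raise AlignmentError(
            f"document mismatch: {set_a.document.doc_id} vs "
            f"{gold.document.doc_id}"
        )
    types = sorted(
        {t.template_type for t in set_a.templates}
        | {t.template_type for t in gold.templates}
    )
    alignments: dict[str, AlignmentResult] = {}
    for tt in types:
        alignments[tt] = align_instances(
            set_a.instances_of(tt),
            gold.instances_of(tt),
            set_a,
            gold,
            schema,
            method=method,
        )
    aligned: set[tuple[str, str]] = set()
    for res in alignments.values():
        aligned |= res.aligned_ids()

    report = SlotAgreementReport()
    for tt in types:
        res = alignments[tt]
        for id_a, id_b, _ in res.pairs:
            inst_a, inst_b = set_a.instance(id_a), gold.instance(id_b)
            for slot, counts in pair_slot_counts(
                inst_a, inst_b, set_a, gold, schema
            ).items():
                report.add(tt, slot, counts)
            _score_complex_slots(report, tt, inst_a, inst_b, aligned)
        for id_a in res.unaligned_a:
            for slot, fill in set_a.instance(id_a).fills:
                report.add(tt, slot, MatchCounts(fp=1))
        for id_b in res.unaligned_b:
            for slot, fill in gold.instance(id_b).fills:
                report.add(tt, slot, MatchCounts(fn=1))
    return report


def _score_complex_slots(
    report: SlotAgreementReport,
    template_type: str,
    inst_a: TemplateInstance,
    inst_b: TemplateInstance,
    aligned: set[tuple[str, str]],
) -> None:
    """Cross-referencing slots of an aligned pair: tp iff referents aligned."""
    refs_a: dict[str, list[str]] = {}
    refs_b: dict[str, list[str]] = {}
    for slot, fill in inst_a.fills:
        if isinstance(fill, TemplateFill):
            refs_a.setdefault(slot, []).append(fill.inst_id)
    for slot, fill in inst_b.fills:
        if isinstance(fill, TemplateFill):
            refs_b.setdefault(slot, []).append(fill.inst_id)
    for slot in sorted(set(refs_a) | set(refs_b)):
        remaining = list(refs_b.get(slot, []))
        tp = 0
        for ra in refs_a.get(slot, []):
            match = next((rb for rb in remaining if (ra, rb) in aligned), None)
            if match is not None:
                remaining.remove(match)
                tp += 1
        report.add(
            template_type,
            slot,
            MatchCounts(
                tp=tp, fp=len(refs_a.get(slot, [])) - tp, fn=len(remaining)
            ),
        )


def score_corpus(
    sets_a: Sequence[AnnotationSet],
    golds: Sequence[AnnotationSet],
    schema: SchemaDef,
    method: AlignmentMethod = "greedy",
) -> SlotAgreementReport:
    """Sum per-document reports over a paired corpus."""
    from .model import pair_by_document

    report = SlotAgreementReport()
    for set_a, gold in pair_by_document(sets_a, golds):
        report = report.merge(
            score_annotation_sets(set_a, gold, schema, method=method)
        )
    return report


def write_template_f1_tsv(
    report: SlotAgreementReport, schema: SchemaDef, path: Union[str, Path]
) -> None:
    """TSV: template type, slot, tp/fp/fn, F1, complex-slot flag; final
    overall micro-averaged F1 row."""
    lines = ["template_type\tslot\ttp\tfp\tfn\tf1\tcomplex_slot"]
    for (tt, slot), counts in sorted(report.per_slot.items()):
        is_complex = ""
        tdef = schema.template_types.get(tt)
        if tdef is not None:
            try:
                is_complex = "yes" if tdef.slot(slot).filler_kind == "template" else "no"
            except KeyError:
                is_complex = "?"
        value = _f1_or_none(counts)
        shown = f"{value:.4f}" if value is not None else "-"
        lines.append(
            f"{tt}\t{slot}\t{counts.tp}\t{counts.fp}\t{counts.fn}\t{shown}"
            f"\t{is_complex}"
        )
    lines.append(f"Overall agreement: Micro-averaged F1\t\t\t\t\t"
                 f"{report.micro_f1:.4f}\t")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
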