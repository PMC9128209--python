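"""Span-level NER evaluation: exact and partial matching with one-to-one
consumption, per-type precision/recall/F1 and micro averages.

*Exact* match: a predicted entity is a true positive iff an unconsumed gold
entity of the same type, start and end exists.  *Partial* match: predictions
are processed in document order and each one consumes the first unconsumed
gold entity of the same type sharing at least one token; a consumed gold
entity is unavailable to later predictions.  Remaining predictions are false
positives, remaining gold entities false negatives.

Evaluation can be restricted to entity types that occur at least a minimum
number of times (default 20) in a training corpus, so that scores are only
reported for types with enough supervision to be learnable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from .model import AnnotationSet, EntityAnnotation, pair_by_document
from .template_agreement import MatchCounts, f1 as _f1

SpanMatchMode = Literal["exact", "partial"]


@dataclass(frozen=True)
class TypeScore:
    counts: MatchCounts
    precision: float
    recall: float
    f1: float
    precision_undefined: bool = False  # no predictions of this type
    recall_undefined: bool = False  # no gold entities of this type


@dataclass(frozen=True)
class NERReport:
    per_type: dict[str, TypeScore]
    mode: str

    @property
    def summed(self) -> MatchCounts:
        total = MatchCounts()
        for score in self.per_type.values():
            total = total + score.counts
        return total

    @property
    def micro(self) -> TypeScore:
        return _score(self.summed)


def _score(counts: MatchCounts) -> TypeScore:
    n_pred = counts.tp + counts.fp
    n_gold = counts.tp + counts.fn
    precision = counts.tp / n_pred if n_pred else 0.0
    recall = counts.tp / n_gold if n_gold else 0.0
    f1_value = _f1(counts) if counts.total else 0.0
    return TypeScore(
        counts=counts,
        precision=precision,
        recall=recall,
        f1=f1_value,
        precision_undefined=n_pred == 0,
        recall_undefined=n_gold == 0,
    )


def _doc_order(entities: Iterable[EntityAnnotation]) -> list[EntityAnnotation]:
    return sorted(entities, key=lambda e: (e.start, e.end, e.category, e.ann_id))


def _counts_exact(
    pred: list[EntityAnnotation], gold: list[EntityAnnotation]
) -> dict[str, MatchCounts]:
    consumed = [False] * len(gold)
    counts: dict[str, Counter] = {}
    for e in _doc_order(pred):
        c = counts.setdefault(e.category, Counter())
        hit = next(
            (
                i
                for i, g in enumerate(gold)
                if not consumed[i]
                and g.category == e.category
                and (g.start, g.end) == (e.start, e.end)
            ),
            None,
        )
        if hit is None:
            c["fp"] += 1
        else:
            consumed[hit] = True
            c["tp"] += 1
    for i, g in enumerate(gold):
        if not consumed[i]:
            counts.setdefault(g.category, Counter())["fn"] += 1
    return {t: MatchCounts(c["tp"], c["fp"], c["fn"]) for t, c in counts.items()}


def _counts_partial(
    pred: list[EntityAnnotation], gold: list[EntityAnnotation]
) -> dict[str, MatchCounts]:
    gold_sorted = _doc_order(gold)
    consumed = [False] * len(gold_sorted)
    counts: dict[str, Counter] = {}
    for e in _doc_order(pred):
        c = counts.setdefault(e.category, Counter())
        hit = next(
            (
                i
                for i, g in enumerate(gold_sorted)
                if not consumed[i] and g.category == e.category and g.overlaps(e)
            ),
            None,
        )
        if hit is None:
            c["fp"] += 1
        else:
            consumed[hit] = True
            c["tp"] += 1
    for i, g in enumerate(gold_sorted):
        if not consumed[i]:
            counts.setdefault(g.category, Counter())["fn"] += 1
    return {t: MatchCounts(c["tp"], c["fp"], c["fn"]) for t, c in counts.items()}


def evaluate_documents(
    pred_sets: Sequence[AnnotationSet],
    gold_sets: Sequence[AnnotationSet],
    mode: SpanMatchMode = "exact",
    types: Optional[set[str]] = None,
) -> NERReport:
    """Score a paired corpus of predicted vs gold entity annotations.

    ``types``, if given, restricts both predictions and gold entities to the
    listed entity types (see :func:`min_count_filter`).
    """
    count_fn = _counts_exact if mode == "exact" else _counts_partial
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown span match mode {mode!r}")
    totals: dict[str, MatchCounts] = {}
    for pred, gold in pair_by_document(pred_sets, gold_sets):
        p_ents = [
            e for e in pred.entities if types is None or e.category in types
        ]
        g_ents = [
            e for e in gold.entities if types is None or e.category in types
        ]
        for t, counts in count_fn(p_ents, g_ents).items():
            totals[t] = totals.get(t, MatchCounts()) + counts
    return NERReport(
        per_type={t: _score(c) for t, c in sorted(totals.items())}, mode=mode
    )


def exact_eval(
    pred: AnnotationSet,
    gold: AnnotationSet,
    types: Optional[set[str]] = None,
) -> NERReport:
    return evaluate_documents([pred], [gold], mode="exact", types=types)


def partial_eval(
    pred: AnnotationSet,
    gold: AnnotationSet,
    types: Optional[set[str]] = None,
) -> NERReport:
    return evaluate_documents([pred], [gold], mode="partial", types=types)


def min_count_filter(
    training: Sequence[AnnotationSet], threshold: int = 20
) -> set[str]:
    """Entity types occurring at least ``threshold`` times in training."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts: Counter = Counter()
    for aset in training:
        counts.update(e.category for e in aset.entities)
    return {t for t, n in counts.items() if n >= threshold}


def write_ner_tsv(report: NERReport, path: Union[str, Path]) -> None:
    """TSV: entity type, precision, recall, F1; final micro-average row."""
    lines = ["entity\tprecision\trecall\tf1"]
    for entity_type, score in report.per_type.items():
        lines.append(
            f"{entity_type}\t{score.precision:.2f}\t{score.recall:.2f}"
            f"\t{score.f1:.2f}"
        )
    micro = report.micro
    lines.append(
        f"Micro average\t{micro.precision:.2f}\t{micro.recall:.2f}"
        f"\t{micro.f1:.2f}"
    )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
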