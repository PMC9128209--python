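"""Core data model for schema-based clinical-trial annotations.

A document carries two layers of annotation:

* *single (atomic) entities* — text spans labelled with a category that is
  either an ontology individual (e.g. ``Bimatoprost``, an individual of class
  ``Drug``) or a literal value (e.g. a ``DoseValue`` such as ``"0.03"``);
* *complex entities* — slot-filling template instances (``Arm``,
  ``Intervention``, ``Medication``, ...) whose typed slots hold single
  entities, literal strings, or references to other template instances.

Spans are 0-based half-open token intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Union


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation sets."""


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise AnnotationError(
                f"token {self.index!r}: empty character span "
                f"[{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class Document:
    """A tokenized source text, identified by PMID where available."""

    doc_id: str
    tokens: tuple[Token, ...]
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise AnnotationError("doc_id must be non-empty")
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise AnnotationError(
                    f"document {self.doc_id}: token indices not contiguous at {i}"
                )
            if tok.char_end > len(self.text):
                raise AnnotationError(
                    f"document {self.doc_id}: token {i} exceeds text length"
                )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class EntityAnnotation:
    """A single-entity annotation over a token span.

    Overlapping and embedded annotations (same or different category) are
    permitted; agreement scoring handles them by token-level union.
    """

    ann_id: str
    category: str
    start: int
    end: int
    surface: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"entity {self.ann_id}: invalid span [{self.start}, {self.end})"
            )

    def tokens_covered(self) -> range:
        return range(self.start, self.end)

    def overlaps(self, other: "EntityAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


# -- slot fills ---------------------------------------------------------------
#
# A slot of a template instance can hold
#   EntityFill     — a reference to an EntityAnnotation in the same set;
#   TemplateFill   — a reference to another TemplateInstance;
#   LiteralFill    — a bare literal string (e.g. "once daily");
#   IndividualFill — a value-bearing fill naming an ontology individual
#                    directly.  Produced when templates are reconstructed
#                    from RDF, where token spans are no longer available.


@dataclass(frozen=True)
class EntityFill:
    ann_id: str


@dataclass(frozen=True)
class TemplateFill:
    inst_id: str


@dataclass(frozen=True)
class LiteralFill:
    value: str


@dataclass(frozen=True)
class IndividualFill:
    name: str


Filler = Union[EntityFill, TemplateFill, LiteralFill, IndividualFill]


@dataclass(frozen=True)
class TemplateInstance:
    """An instance of a complex-entity template with its slot fills."""

    inst_id: str
    template_type: str
    fills: tuple[tuple[str, Filler], ...] = ()

    def fills_for(self, slot_name: str) -> list[Filler]:
        return [f for s, f in self.fills if s == slot_name]

    def slot_names(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.fills:
            if s not in seen:
                seen.append(s)
        return seen


@dataclass
class AnnotationSet:
    """One annotator's entities and template instances over one document."""

    document: Document
    annotator_id: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    templates: list[TemplateInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate_references()

    def validate_references(self) -> None:
        ent_ids = [e.ann_id for e in self.entities]
        inst_ids = [t.inst_id for t in self.templates]
        if len(set(ent_ids)) != len(ent_ids):
            raise AnnotationError(
                f"{self.document.doc_id}/{self.annotator_id}: duplicate entity ids"
            )
        if len(set(inst_ids)) != len(inst_ids):
            raise AnnotationError(
                f"{self.document.doc_id}/{self.annotator_id}: duplicate instance ids"
            )
        n_tok = len(self.document)
        for e in self.entities:
            if e.end > n_tok:
                raise AnnotationError(
                    f"entity {e.ann_id}: span [{e.start}, {e.end}) exceeds "
                    f"{n_tok} tokens of {self.document.doc_id}"
                )
        known_ents = set(ent_ids)
        known_insts = set(inst_ids)
        for t in self.templates:
            for slot, fill in t.fills:
                if isinstance(fill, EntityFill) and fill.ann_id not in known_ents:
                    raise AnnotationError(
                        f"instance {t.inst_id} slot {slot}: dangling entity "
                        f"reference {fill.ann_id!r}"
                    )
                if isinstance(fill, TemplateFill) and fill.inst_id not in known_insts:
                    raise AnnotationError(
                        f"instance {t.inst_id} slot {slot}: dangling template "
                        f"reference {fill.inst_id!r}"
                    )

    def entity(self, ann_id: str) -> EntityAnnotation:
        for e in self.entities:
            if e.ann_id == ann_id:
                return e
        raise KeyError(ann_id)

    def instance(self, inst_id: str) -> TemplateInstance:
        for t in self.templates:
            if t.inst_id == inst_id:
                return t
        raise KeyError(inst_id)

    def instances_of(self, template_type: str) -> list[TemplateInstance]:
        return [t for t in self.templates if t.template_type == template_type]

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(
            document=self.document,
            annotator_id=self.annotator_id,
            entities=list(self.entities),
            templates=[replace(t) for t in self.templates],
        )


def pair_by_document(
    sets_a: Iterable[AnnotationSet], sets_b: Iterable[AnnotationSet]
) -> Iterator[tuple[AnnotationSet, AnnotationSet]]:
    """Pair two annotators' sets by doc_id; raise if the corpora differ."""
    by_id_a = {s.document.doc_id: s for s in sets_a}
    by_id_b = {s.document.doc_id: s for s in sets_b}
    if by_id_a.keys() != by_id_b.keys():
        only_a = sorted(by_id_a.keys() - by_id_b.keys())
        only_b = sorted(by_id_b.keys() - by_id_a.keys())
        raise AnnotationError(
            f"annotator corpora cover different documents "
            f"(only A: {only_a}, only B: {only_b})"
        )
    for doc_id in sorted(by_id_a):
        yield by_id_a[doc_id], by_id_b[doc_id]
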