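"""Template annotations as RDF triples, serialized as W3C N-Triples.

Each template instance becomes one ``rdf:type`` statement plus one statement
per slot fill, e.g. for the bimatoprost arm of a glaucoma trial::

    data:Arm_bimatoprost  rdf:type             ctro:Arm
    data:Arm_bimatoprost  ctro:hasIntervention data:Intervention_bimatoprost
    data:Intervention_bimatoprost ctro:hasFrequency "once daily"
    data:Medication_bimatoprost   ctro:hasDrug      data:Bimatoprost

Entity fills whose category is an ontology individual map to individual
IRIs in the data namespace; literal-valued fills map to plain quoted
literals.  The ``ctro:`` and ``data:`` namespace bases are configurable;
reading keys on local names, so any base round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union
from urllib.parse import quote

from rdflib import Graph, Literal, URIRef
from rdflib.plugins.serializers.nt import _nt_row

from .model import (
    AnnotationSet,
    Document,
    EntityFill,
    Filler,
    IndividualFill,
    LiteralFill,
    TemplateFill,
    TemplateInstance,
)
from .schema import SchemaDef

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"


class RdfMappingError(ValueError):
    """Raised when triples cannot be mapped onto the schema."""


@dataclass(frozen=True)
class NamespaceConfig:
    """IRI bases for the ontology (classes/properties) and the data."""

    ctro: str = "http://example.org/ctro#"
    data: str = "http://example.org/data#"

    def class_iri(self, name: str) -> str:
        return self.ctro + quote(name, safe="")

    def data_iri(self, name: str) -> str:
        return self.data + quote(name, safe="")


def local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            tail = iri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri


@dataclass(frozen=True)
class Triple:
    """One ⟨subject, predicate, object⟩ statement.

    ``object_is_literal`` distinguishes a quoted literal from an IRI object.
    """

    subject: str
    predicate: str
    object: str
    object_is_literal: bool = False

    def to_ntriples(self) -> str:
        o = Literal(self.object) if self.object_is_literal else URIRef(self.object)
        return _nt_row((URIRef(self.subject), URIRef(self.predicate), o)).rstrip("\n")


def normalize_literal(value: str) -> str:
    """Collapse surrounding/internal runs of whitespace to single spaces."""
    return " ".join(value.split())


def _fill_object(
    fill: Filler, context: AnnotationSet, schema: SchemaDef, ns: NamespaceConfig
) -> tuple[str, bool]:
    if isinstance(fill, LiteralFill):
        return fill.value, True
    if isinstance(fill, TemplateFill):
        return ns.data_iri(fill.inst_id), False
    if isinstance(fill, IndividualFill):
        return ns.data_iri(fill.name), False
    if isinstance(fill, EntityFill):
        try:
            ent = context.entity(fill.ann_id)
        except KeyError:
            raise RdfMappingError(
                f"unresolvable entity reference {fill.ann_id!r}"
            ) from None
        cat = schema.categories.get(ent.category)
        if cat is None:
            raise RdfMappingError(f"entity {ent.ann_id}: unknown category")
        if cat.kind == "individual":
            return ns.data_iri(ent.category), False
        return normalize_literal(ent.surface), True
    raise RdfMappingError(f"unrecognised fill {fill!r}")


def templates_to_triples(
    annotation_set: AnnotationSet,
    schema: SchemaDef,
    ns: NamespaceConfig = NamespaceConfig(),
) -> list[Triple]:
    """Export template instances: one type triple each plus one per fill.

    The triple count always equals instance count + total fill count.
    Order is deterministic: instances in set order, the type triple first.
    """
    triples: list[Triple] = []
    for inst in annotation_set.templates:
        subject = ns.data_iri(inst.inst_id)
        triples.append(
            Triple(subject, RDF_TYPE, ns.class_iri(inst.template_type))
        )
        for slot, fill in inst.fills:
            obj, is_lit = _fill_object(fill, annotation_set, schema, ns)
            triples.append(Triple(subject, ns.class_iri(slot), obj, is_lit))
    return triples


def triples_to_templates(
    triples: Iterable[Triple],
    schema: SchemaDef,
    ns: NamespaceConfig = NamespaceConfig(),
    doc_id: str = "rdf",
    annotator_id: str = "rdf",
) -> tuple[AnnotationSet, list[str]]:
    """Rebuild template instances from triples (the inverse of export).

    Token spans are not recoverable from RDF, so entity fills come back as
    value-bearing fills (an individual name, or a literal).  A subject used
    as a template without an ``rdf:type`` statement gets its type inferred
    from the referencing slot when that slot allows exactly one type;
    otherwise a :class:`RdfMappingError` is raised.  Predicates that match
    no slot of the subject's template type are collected as warnings.
    """
    triples = list(triples)
    warnings: list[str] = []
    types: dict[str, str] = {}
    order: list[str] = []
    for t in triples:
        subj = local_name(t.subject)
        if subj not in types and t.predicate == RDF_TYPE:
            if t.object_is_literal:
                raise RdfMappingError(f"{subj}: literal rdf:type object")
            cls = local_name(t.object)
            if cls not in schema.template_types:
                raise RdfMappingError(f"{subj}: unknown template type {cls!r}")
            types[subj] = cls
        if subj not in order:
            order.append(subj)

    # Propagate types to untyped instances reachable through template slots
    # whose range is a single type (e.g. an object of hasMedication must be
    # a Medication).  Iterate to a fixed point so chains resolve.
    changed = True
    while changed:
        changed = False
        for t in triples:
            if t.predicate == RDF_TYPE or t.object_is_literal:
                continue
            subj = local_name(t.subject)
            if subj not in types:
                continue
            slot_name = local_name(t.predicate)
            try:
                slot = schema.template_types[types[subj]].slot(slot_name)
            except KeyError:
                continue
            obj = local_name(t.object)
            if slot.filler_kind == "template" and obj not in types:
                allowed = sorted(slot.allowed_types)
                if len(allowed) != 1:
                    raise RdfMappingError(
                        f"{subj}.{slot_name}: cannot infer type of untyped "
                        f"referenced instance {obj!r}"
                    )
                types[obj] = allowed[0]
                if obj not in order:
                    order.append(obj)
                changed = True

    untyped = [s for s in order if s not in types]
    if untyped:
        raise RdfMappingError(
            f"subject(s) without rdf:type statement: {untyped}"
        )

    fills: dict[str, list[tuple[str, Filler]]] = {s: [] for s in order}
    for t in triples:
        if t.predicate == RDF_TYPE:
            continue
        subj = local_name(t.subject)
        slot_name = local_name(t.predicate)
        tt = schema.template_types[types[subj]]
        try:
            slot = tt.slot(slot_name)
        except KeyError:
            warnings.append(
                f"{subj}: predicate {slot_name!r} is not a slot of {tt.name}"
            )
            continue
        if slot.filler_kind == "template":
            if t.object_is_literal:
                raise RdfMappingError(
                    f"{subj}.{slot_name}: literal object in template slot"
                )
            fills[subj].append((slot_name, TemplateFill(local_name(t.object))))
        elif slot.filler_kind == "literal":
            fills[subj].append((slot_name, LiteralFill(str(t.object))))
        else:  # entity slot
            if t.object_is_literal:
                fills[subj].append(
                    (slot_name, LiteralFill(normalize_literal(str(t.object))))
                )
            else:
                fills[subj].append(
                    (slot_name, IndividualFill(local_name(t.object)))
                )

    instances = [
        TemplateInstance(
            inst_id=subj, template_type=types[subj], fills=tuple(fills[subj])
        )
        for subj in order
    ]
    doc = Document(doc_id=doc_id, tokens=(), text="")
    aset = AnnotationSet(
        document=doc, annotator_id=annotator_id, entities=[], templates=instances
    )
    return aset, warnings


# -- file I/O ----------------------------------------------------------------


def dumps_ntriples(triples: Iterable[Triple]) -> str:
    return "".join(t.to_ntriples() + "\n" for t in triples)


def write_ntriples(triples: Iterable[Triple], path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_ntriples(triples), encoding="utf-8")


def loads_ntriples(text: str) -> list[Triple]:
    graph = Graph()
    graph.parse(data=text, format="nt")
    out = []
    for s, p, o in graph:
        out.append(
            Triple(
                subject=str(s),
                predicate=str(p),
                object=str(o),
                object_is_literal=isinstance(o, Literal),
            )
        )
    # rdflib stores a set; impose a stable order
    out.sort(key=lambda t: (t.subject, t.predicate != RDF_TYPE, t.predicate, t.object))
    return out


def read_ntriples(path: Union[str, Path]) -> list[Triple]:
    return loads_ntriples(Path(path).read_text(encoding="utf-8"))
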