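"""Annotation schema: entity categories, template types, slot constraints.

The schema is data, not code: it is read from a YAML file with three
sections —

``categories``
    list of ``{name, parent, kind}`` where ``kind`` is ``individual`` or
    ``literal`` and the ``parent`` links form a forest (the subsumption
    hierarchy, e.g. *DisorderOrSyndrome* > *Glaucoma* > *AngleClosureGlaucoma*);
``templates``
    list of ``{name, slots: [{name, filler_kind, allowed_types, functional}]}``
    where ``filler_kind`` is ``entity``, ``template`` or ``literal``;
``grouping``
    optional mapping from a category to the general (ancestor) category that
    agreement statistics are tabulated under.  Categories without an entry
    default to their topmost ancestor.

Two configurations ship with the package: ``mini`` (a small trial-shaped
schema used by the synthetic corpus generator and the examples) and ``ctro``
(a fuller schema shaped after the C-TrO clinical-trial ontology).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .model import (
    AnnotationSet,
    EntityFill,
    IndividualFill,
    LiteralFill,
    TemplateFill,
    TemplateInstance,
)

ENTITY_KINDS = ("individual", "literal")
FILLER_KINDS = ("entity", "template", "literal")


class SchemaError(ValueError):
    """Raised when a schema configuration is malformed or inconsistent."""


@dataclass(frozen=True)
class EntityCategory:
    name: str
    parent: Optional[str] = None
    kind: str = "individual"


@dataclass(frozen=True)
class SlotDef:
    name: str
    filler_kind: str
    allowed_types: frozenset[str]
    functional: bool = False


@dataclass(frozen=True)
class TemplateTypeDef:
    name: str
    slots: tuple[SlotDef, ...]

    def slot(self, name: str) -> SlotDef:
        for s in self.slots:
            if s.name == name:
                return s
        raise KeyError(name)

    def slot_names(self) -> list[str]:
        return [s.name for s in self.slots]


@dataclass(frozen=True)
class Violation:
    """One constraint violation found in a template instance."""

    inst_id: str
    slot: str
    reason: str


@dataclass
class SchemaDef:
    categories: dict[str, EntityCategory] = field(default_factory=dict)
    template_types: dict[str, TemplateTypeDef] = field(default_factory=dict)
    grouping: dict[str, str] = field(default_factory=dict)

    # -- hierarchy ------------------------------------------------------

    def ancestors(self, category: str) -> list[str]:
        """The category itself followed by its ancestors up to the root."""
        if category not in self.categories:
            raise KeyError(f"unknown category {category!r}")
        chain = [category]
        cur = self.categories[category]
        while cur.parent is not None:
            chain.append(cur.parent)
            cur = self.categories[cur.parent]
        return chain

    def group_category(self, category: str) -> str:
        """Map a category to the general category used for agreement.

        Explicit ``grouping`` entries win; otherwise the topmost ancestor.
        Idempotent: the group of a group is itself.
        """
        if category in self.grouping:
            return self.grouping[category]
        return self.ancestors(category)[-1]

    def group_names(self) -> list[str]:
        return sorted({self.group_category(c) for c in self.categories})

    def is_subtype(self, category: str, allowed: Iterable[str]) -> bool:
        allowed = set(allowed)
        return any(a in allowed for a in self.ancestors(category))

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        for cat in self.categories.values():
            if cat.kind not in ENTITY_KINDS:
                raise SchemaError(f"category {cat.name}: bad kind {cat.kind!r}")
            if cat.parent is not None and cat.parent not in self.categories:
                raise SchemaError(
                    f"category {cat.name}: unknown parent {cat.parent!r}"
                )
        for name in self.categories:
            # cycle check: the ancestor walk must terminate
            seen = set()
            cur: Optional[str] = name
            while cur is not None:
                if cur in seen:
                    raise SchemaError(f"category {name}: parent cycle via {cur}")
                seen.add(cur)
                cur = self.categories[cur].parent
        for tt in self.template_types.values():
            slot_names = [s.name for s in tt.slots]
            if len(set(slot_names)) != len(slot_names):
                raise SchemaError(f"template {tt.name}: duplicate slot names")
            for slot in tt.slots:
                if slot.filler_kind not in FILLER_KINDS:
                    raise SchemaError(
                        f"template {tt.name} slot {slot.name}: bad filler_kind "
                        f"{slot.filler_kind!r}"
                    )
                if not slot.allowed_types:
                    raise SchemaError(
                        f"template {tt.name} slot {slot.name}: empty allowed_types"
                    )
                universe = (
                    self.template_types
                    if slot.filler_kind == "template"
                    else self.categories
                )
                if slot.filler_kind == "literal":
                    continue
                for t in slot.allowed_types:
                    if t not in universe:
                        raise SchemaError(
                            f"template {tt.name} slot {slot.name}: unknown "
                            f"allowed type {t!r}"
                        )
        for cat, target in self.grouping.items():
            if cat not in self.categories:
                raise SchemaError(f"grouping: unknown category {cat!r}")
            if target not in self.ancestors(cat):
                raise SchemaError(
                    f"grouping: {target!r} is not an ancestor of {cat!r}"
                )

    def validate_instance(
        self, instance: TemplateInstance, context: AnnotationSet
    ) -> list[Violation]:
        """Check one template instance against slot typing and cardinality.

        Returns an empty list iff every fill is of an allowed type, every
        functional slot holds at most one fill, and every reference resolves
        in ``context``.  An unknown template type is a hard error, not a
        violation record.
        """
        if instance.template_type not in self.template_types:
            raise KeyError(f"unknown template type {instance.template_type!r}")
        tt = self.template_types[instance.template_type]
        violations: list[Violation] = []
        known_slots = set(tt.slot_names())
        for slot_name in instance.slot_names():
            if slot_name not in known_slots:
                violations.append(
                    Violation(instance.inst_id, slot_name, "unknown slot")
                )
                continue
            slot = tt.slot(slot_name)
            fills = instance.fills_for(slot_name)
            if slot.functional and len(fills) > 1:
                violations.append(
                    Violation(
                        instance.inst_id,
                        slot_name,
                        f"functional slot holds {len(fills)} fills",
                    )
                )
            for fill in fills:
                violations.extend(
                    self._check_fill(instance.inst_id, slot, fill, context)
                )
        return violations

    def _check_fill(self, inst_id, slot, fill, context) -> list[Violation]:
        if isinstance(fill, LiteralFill):
            if slot.filler_kind == "literal":
                return []
            # entity slots whose allowed categories are literal-valued get
            # value-bearing literal fills back from RDF (spans are lost)
            if slot.filler_kind == "entity" and any(
                self.categories.get(t) is not None
                and self.categories[t].kind == "literal"
                for t in slot.allowed_types
            ):
                return []
            return [
                Violation(inst_id, slot.name, "literal fill in non-literal slot")
            ]
        if isinstance(fill, TemplateFill):
            if slot.filler_kind != "template":
                return [
                    Violation(
                        inst_id, slot.name, "template fill in non-template slot"
                    )
                ]
            try:
                ref = context.instance(fill.inst_id)
            except KeyError:
                return [
                    Violation(
                        inst_id, slot.name, f"dangling reference {fill.inst_id!r}"
                    )
                ]
            if ref.template_type not in slot.allowed_types:
                return [
                    Violation(
                        inst_id,
                        slot.name,
                        f"filler type {ref.template_type} not allowed",
                    )
                ]
            return []
        if isinstance(fill, (EntityFill, IndividualFill)):
            if slot.filler_kind != "entity":
                return [
                    Violation(inst_id, slot.name, "entity fill in non-entity slot")
                ]
            if isinstance(fill, EntityFill):
                try:
                    category = context.entity(fill.ann_id).category
                except KeyError:
                    return [
                        Violation(
                            inst_id,
                            slot.name,
                            f"dangling reference {fill.ann_id!r}",
                        )
                    ]
            else:
                category = fill.name
            if category not in self.categories:
                return [
                    Violation(
                        inst_id, slot.name, f"unknown category {category!r}"
                    )
                ]
            if not self.is_subtype(category, slot.allowed_types):
                return [
                    Violation(
                        inst_id,
                        slot.name,
                        f"filler category {category} not allowed",
                    )
                ]
            return []
        return [Violation(inst_id, slot.name, f"unrecognised fill {fill!r}")]

    def validate_set(self, annotation_set: AnnotationSet) -> list[Violation]:
        out: list[Violation] = []
        for inst in annotation_set.templates:
            out.extend(self.validate_instance(inst, annotation_set))
        for ent in annotation_set.entities:
            if ent.category not in self.categories:
                out.append(
                    Violation(ent.ann_id, "", f"unknown category {ent.category!r}")
                )
        return out


# -- serialization -----------------------------------------------------------


def _parse_schema_dict(data: Mapping) -> SchemaDef:
    if not isinstance(data, Mapping):
        raise SchemaError("schema config must be a mapping")
    categories: dict[str, EntityCategory] = {}
    for row in data.get("categories", []) or []:
        name = row.get("name")
        if not name:
            raise SchemaError(f"category entry without a name: {row!r}")
        if name in categories:
            raise SchemaError(f"duplicate category {name!r}")
        categories[name] = EntityCategory(
            name=name,
            parent=row.get("parent"),
            kind=row.get("kind", "individual"),
        )
    template_types: dict[str, TemplateTypeDef] = {}
    for row in data.get("templates", []) or []:
        name = row.get("name")
        if not name:
            raise SchemaError(f"template entry without a name: {row!r}")
        if name in template_types:
            raise SchemaError(f"duplicate template type {name!r}")
        slots = []
        for srow in row.get("slots", []) or []:
            if "name" not in srow or "filler_kind" not in srow:
                raise SchemaError(
                    f"template {name}: slot needs name and filler_kind: {srow!r}"
                )
            allowed = srow.get("allowed_types") or []
            if srow["filler_kind"] == "literal" and not allowed:
                allowed = ["string"]
            slots.append(
                SlotDef(
                    name=srow["name"],
                    filler_kind=srow["filler_kind"],
                    allowed_types=frozenset(allowed),
                    functional=bool(srow.get("functional", False)),
                )
            )
        template_types[name] = TemplateTypeDef(name=name, slots=tuple(slots))
    grouping = dict(data.get("grouping", {}) or {})
    schema = SchemaDef(
        categories=categories, template_types=template_types, grouping=grouping
    )
    schema.validate()
    return schema


def load_schema(source: Union[str, Path, io.TextIOBase]) -> SchemaDef:
    """Load and validate a schema from a YAML file, path or stream.

    Pass ``"mini"`` or ``"ctro"`` to load a bundled configuration.
    """
    if isinstance(source, str) and source in ("mini", "ctro"):
        text = (
            resources.files("ctroeval.data")
            .joinpath(f"{source}_schema.yaml")
            .read_text(encoding="utf-8")
        )
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise SchemaError(f"cannot parse schema config{line}: {exc}") from exc
    return _parse_schema_dict(data)


def serialize_schema(schema: SchemaDef) -> str:
    """Dump a SchemaDef to YAML; ``load_schema`` round-trips it."""
    data = {
        "categories": [
            {"name": c.name, "parent": c.parent, "kind": c.kind}
            for c in schema.categories.values()
        ],
        "templates": [
            {
                "name": tt.name,
                "slots": [
                    {
                        "name": s.name,
                        "filler_kind": s.filler_kind,
                        "allowed_types": sorted(s.allowed_types),
                        "functional": s.functional,
                    }
                    for s in tt.slots
                ],
            }
            for tt in schema.template_types.values()
        ],
        "grouping": dict(schema.grouping),
    }
    return yaml.safe_dump(data, sort_keys=False)


def group_category(schema: SchemaDef, category: str) -> str:
    return schema.group_category(category)
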