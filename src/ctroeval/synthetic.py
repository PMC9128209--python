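"""Synthetic two-annotator corpora with known disagreement rates.

The generator emulates the *statistical and structural* shape of a
schema-annotated clinical-trial abstract corpus over the bundled ``mini``
schema: tokenized documents, single-entity spans (including overlapping and
embedded ones), and a nested template structure per document

    Publication -> ClinicalTrial -> {Population, Arm*, DiffBetweenGroups}
    Arm -> Intervention -> Medication;  Arm -> Outcome -> Endpoint

A second annotator (or a prediction run) is simulated by perturbing the
gold standard with independent, per-item disagreement operations that
mirror the disagreement causes observed between human annotators: missed
entities, category confusion, span-boundary jitter, dropped templates,
missed slot fills and wrong slot-filler choices.  Every perturbation is
logged, rates are recoverable from the scorers, and a single integer seed
fixes all randomness (per-document sub-streams are split off it, so
corpora of different sizes share a prefix).

Surface text is synthetic vocabulary; the scorers never read semantics,
only categories, spans, values and structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .conll import document_from_token_texts
from .model import (
    AnnotationSet,
    EntityAnnotation,
    EntityFill,
    Filler,
    LiteralFill,
    TemplateFill,
    TemplateInstance,
)
from .schema import SchemaDef, load_schema


class GeneratorConfigError(ValueError):
    pass


#: Per-token start rates of single-entity spans, by category.
DEFAULT_ENTITY_RATES: dict[str, float] = {
    "Bimatoprost": 0.010,
    "Timolol": 0.010,
    "Latanoprost": 0.008,
    "Glaucoma": 0.010,
    "Percentage": 0.008,
    "Mean": 0.005,
    "Country": 0.005,
    "DoseValue": 0.015,
    "ChangeValue": 0.015,
    "TimePoint": 0.015,
    "EndPointDescription": 0.008,
    "Precondition": 0.008,
    "ConclusionComment": 0.005,
    "NumberPatientsArm": 0.008,
    "Author": 0.008,
    "Title": 0.004,
    "PMID": 0.004,
    "PublicationYear": 0.004,
}


@dataclass(frozen=True)
class PerturbationConfig:
    """Independent per-item disagreement rates, each in [0, 1]."""

    p_drop_entity: float = 0.0
    p_type_swap: float = 0.0
    p_boundary_shift: float = 0.0
    boundary_offsets: tuple[int, ...] = (-1, 1)
    boundary_categories: Optional[tuple[str, ...]] = None
    p_drop_template: float = 0.0
    p_drop_slot: float = 0.0
    p_swap_filler: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_drop_entity",
            "p_type_swap",
            "p_boundary_shift",
            "p_drop_template",
            "p_drop_slot",
            "p_swap_filler",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 10
    tokens_per_doc: tuple[int, int] = (120, 200)
    entity_rate_per_category: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_RATES)
    )
    entity_len_range: tuple[int, int] = (1, 3)
    p_overlap: float = 0.08  # chance of an extra overlapping/embedded twin
    n_arms: int = 2
    slot_fill_prob: float = 0.9
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)


@dataclass(frozen=True)
class PerturbationEvent:
    kind: str
    target: str
    detail: str = ""


@dataclass
class SyntheticPair:
    gold: AnnotationSet
    other: AnnotationSet
    log: list[PerturbationEvent]


_VOCAB = [f"w{i:02d}" for i in range(40)] + [
    f"{a}.{b}" for a in range(3) for b in (1, 5, 9)
]


def _doc_rngs(config: GeneratorConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(config.n_docs)
    return [np.random.default_rng(c) for c in children]


class _DocBuilder:
    """Builds one gold AnnotationSet; all randomness from one Generator."""

    def __init__(
        self, doc_id: str, config: GeneratorConfig, schema: SchemaDef,
        rng: np.random.Generator,
    ):
        self.config = config
        self.schema = schema
        self.rng = rng
        n_tok = int(
            rng.integers(config.tokens_per_doc[0], config.tokens_per_doc[1] + 1)
        )
        texts = [ _VOCAB[int(rng.integers(0, len(_VOCAB)))] for _ in range(n_tok) ]
        self.document = document_from_token_texts(doc_id, texts)
        self.entities: list[EntityAnnotation] = []
        self.templates: list[TemplateInstance] = []
        self._eid = 0
        self._tid = 0

    # -- entities -------------------------------------------------------

    def _new_entity(self, category: str, start: int, end: int) -> EntityAnnotation:
        self._eid += 1
        ent = EntityAnnotation(
            ann_id=f"e{self._eid:03d}",
            category=category,
            start=start,
            end=end,
            surface=" ".join(
                t.text for t in self.document.tokens[start:end]
            ),
        )
        self.entities.append(ent)
        return ent

    def place_entities(self) -> None:
        n_tok = len(self.document)
        lo, hi = self.config.entity_len_range
        for category in sorted(self.config.entity_rate_per_category):
            rate = self.config.entity_rate_per_category[category]
            if category not in self.schema.categories:
                raise GeneratorConfigError(f"unknown category {category!r}")
            n = int(self.rng.binomial(n_tok, rate))
            for _ in range(n):
                length = int(self.rng.integers(lo, hi + 1))
                start = int(self.rng.integers(0, max(1, n_tok - length)))
                ent = self._new_entity(category, start, min(start + length, n_tok))
                if self.rng.random() < self.config.p_overlap:
                    # overlapping or embedded twin of the same category
                    shift = int(self.rng.integers(0, ent.end - ent.start))
                    end2 = min(ent.end + 1, n_tok)
                    if ent.start + shift < end2:
                        self._new_entity(category, ent.start + shift, end2)

    def _entity_of(self, allowed: frozenset[str]) -> EntityAnnotation:
        pool = [
            e
            for e in self.entities
            if self.schema.is_subtype(e.category, allowed)
        ]
        if pool:
            return pool[int(self.rng.integers(0, len(pool)))]
        # no span of a suitable category yet: create one
        candidates = [
            c
            for c in sorted(self.schema.categories)
            if self.schema.is_subtype(c, allowed)
            and not any(
                self.schema.categories[ch].parent == c
                for ch in self.schema.categories
            )
        ]
        if not candidates:
            raise GeneratorConfigError(
                f"no generatable filler for allowed types {sorted(allowed)}"
            )
        category = candidates[int(self.rng.integers(0, len(candidates)))]
        n_tok = len(self.document)
        start = int(self.rng.integers(0, n_tok))
        return self._new_entity(category, start, min(start + 1, n_tok))

    # -- templates ------------------------------------------------------

    def _new_instance(
        self, template_type: str, fills: list[tuple[str, Filler]]
    ) -> TemplateInstance:
        self._tid += 1
        inst = TemplateInstance(
            inst_id=f"{template_type}_{self._tid:02d}",
            template_type=template_type,
            fills=tuple(fills),
        )
        self.templates.append(inst)
        return inst

    def _maybe(self) -> bool:
        return bool(self.rng.random() < self.config.slot_fill_prob)

    def _entity_fill(
        self, fills: list, template_type: str, slot_name: str
    ) -> None:
        slot = self.schema.template_types[template_type].slot(slot_name)
        if self._maybe():
            fills.append((slot_name, EntityFill(self._entity_of(slot.allowed_types).ann_id)))

    def _literal_fill(self, fills: list, slot_name: str) -> None:
        if self._maybe():
            value = f"v{int(self.rng.integers(0, 40)):02d}"
            fills.append((slot_name, LiteralFill(value)))

    def build_templates(self) -> None:
        cfg = self.config
        endpoint_fills: list[tuple[str, Filler]] = []
        self._entity_fill(endpoint_fills, "Endpoint", "hasEndoPointDescription")
        self._entity_fill(endpoint_fills, "Endpoint", "hasAggregationMethod")
        endpoint = self._new_instance("Endpoint", endpoint_fills)

        arms, outcomes = [], []
        for _ in range(cfg.n_arms):
            med_fills: list[tuple[str, Filler]] = []
            self._entity_fill(med_fills, "Medication", "hasDrug")
            self._literal_fill(med_fills, "hasDoseValue")
            self._entity_fill(med_fills, "Medication", "hasDoseUnit")
            medication = self._new_instance("Medication", med_fills)

            int_fills: list[tuple[str, Filler]] = [
                ("hasMedication", TemplateFill(medication.inst_id))
            ]
            self._literal_fill(int_fills, "hasFrequency")
            intervention = self._new_instance("Intervention", int_fills)

            out_fills: list[tuple[str, Filler]] = [
                ("hasEndpoint", TemplateFill(endpoint.inst_id))
            ]
            self._literal_fill(out_fills, "hasChangeValue")
            self._entity_fill(out_fills, "Outcome", "hasTimePoint")
            outcome = self._new_instance("Outcome", out_fills)
            outcomes.append(outcome)

            arm_fills: list[tuple[str, Filler]] = [
                ("hasIntervention", TemplateFill(intervention.inst_id)),
                ("hasOutcome", TemplateFill(outcome.inst_id)),
            ]
            self._entity_fill(arm_fills, "Arm", "hasNumberPatientsArm")
            arms.append(self._new_instance("Arm", arm_fills))

        pop_fills: list[tuple[str, Filler]] = []
        self._entity_fill(pop_fills, "Population", "hasPrecondition")
        self._entity_fill(pop_fills, "Population", "hasCountry")
        population = self._new_instance("Population", pop_fills)

        diff = None
        if len(outcomes) >= 2:
            diff_fills: list[tuple[str, Filler]] = [
                ("hasOutcome1", TemplateFill(outcomes[0].inst_id)),
                ("hasOutcome2", TemplateFill(outcomes[1].inst_id)),
            ]
            self._literal_fill(diff_fills, "hasPvalueDiff")
            diff = self._new_instance("DiffBetweenGroups", diff_fills)

        ct_fills: list[tuple[str, Filler]] = [
            ("hasArm", TemplateFill(a.inst_id)) for a in arms
        ]
        ct_fills.append(("hasPopulation", TemplateFill(population.inst_id)))
        if diff is not None:
            ct_fills.append(("hasDiffBetweenGroups", TemplateFill(diff.inst_id)))
        self._entity_fill(ct_fills, "ClinicalTrial", "hasConclusionComment")
        self._entity_fill(ct_fills, "ClinicalTrial", "analysesHealthCondition")
        trial = self._new_instance("ClinicalTrial", ct_fills)

        pub_fills: list[tuple[str, Filler]] = [
            ("describes", TemplateFill(trial.inst_id))
        ]
        self._entity_fill(pub_fills, "Publication", "hasAuthor")
        self._entity_fill(pub_fills, "Publication", "hasTitle")
        self._entity_fill(pub_fills, "Publication", "hasPMID")
        self._entity_fill(pub_fills, "Publication", "hasPublicationYear")
        self._new_instance("Publication", pub_fills)

    def build(self, annotator_id: str) -> AnnotationSet:
        self.place_entities()
        self.build_templates()
        return AnnotationSet(
            document=self.document,
            annotator_id=annotator_id,
            entities=self.entities,
            templates=self.templates,
        )


def generate_gold(
    config: GeneratorConfig,
    schema: Optional[SchemaDef] = None,
    annotator_id: str = "annotator1",
) -> list[AnnotationSet]:
    """Generate ``config.n_docs`` schema-valid gold annotation sets."""
    if schema is None:
        schema = load_schema("mini")
    sets = []
    for i, rng in enumerate(_doc_rngs(config)):
        builder = _DocBuilder(f"doc{i:04d}", config, schema, rng)
        sets.append(builder.build(annotator_id))
    return sets


# -- perturbation ------------------------------------------------------------


def perturb(
    gold: AnnotationSet,
    config: GeneratorConfig,
    seed: int,
    schema: Optional[SchemaDef] = None,
    annotator_id: str = "annotator2",
) -> SyntheticPair:
    """Derive a disagreeing second annotator from a gold set.

    Each operation is applied independently per item at its configured rate;
    the returned log records every applied change.  With all rates zero the
    result is a deep copy.
    """
    if schema is None:
        schema = load_schema("mini")
    p = config.perturbation
    rng = np.random.default_rng(seed)
    log: list[PerturbationEvent] = []

    entities: list[EntityAnnotation] = []
    dropped_entities: set[str] = set()
    n_tok = len(gold.document)
    swap_pool = sorted(
        c for c, rate in config.entity_rate_per_category.items() if rate > 0
    ) or sorted(gold_categories(gold))
    for ent in gold.entities:
        if rng.random() < p.p_drop_entity:
            dropped_entities.add(ent.ann_id)
            log.append(PerturbationEvent("drop_entity", ent.ann_id, ent.category))
            continue
        new = ent
        if rng.random() < p.p_type_swap:
            choices = [
                c
                for c in swap_pool
                if c != ent.category
                and schema.categories[c].kind
                == schema.categories[ent.category].kind
            ]
            if choices:
                swapped = choices[int(rng.integers(0, len(choices)))]
                log.append(
                    PerturbationEvent(
                        "type_swap", ent.ann_id, f"{ent.category}->{swapped}"
                    )
                )
                new = replace(new, category=swapped)
        shiftable = (
            p.boundary_categories is None
            or new.category in p.boundary_categories
        )
        if shiftable and rng.random() < p.p_boundary_shift:
            offset = int(
                p.boundary_offsets[int(rng.integers(0, len(p.boundary_offsets)))]
            )
            new_end = min(max(new.end + offset, new.start + 1), n_tok)
            if new_end != new.end:
                log.append(
                    PerturbationEvent(
                        "boundary_shift", ent.ann_id, f"end{offset:+d}"
                    )
                )
                new = replace(
                    new,
                    end=new_end,
                    surface=" ".join(
                        t.text for t in gold.document.tokens[new.start:new_end]
                    ),
                )
        entities.append(new)

    templates: list[TemplateInstance] = []
    dropped_templates: set[str] = set()
    for inst in gold.templates:
        if rng.random() < p.p_drop_template:
            dropped_templates.add(inst.inst_id)
            log.append(
                PerturbationEvent("drop_template", inst.inst_id, inst.template_type)
            )
            continue
        templates.append(inst)

    kept_entity_ids = {e.ann_id for e in entities}
    final_templates: list[TemplateInstance] = []
    for inst in templates:
        fills: list[tuple[str, Filler]] = []
        for slot, fill in inst.fills:
            if isinstance(fill, EntityFill) and fill.ann_id in dropped_entities:
                continue  # the annotator never saw this entity
            if (
                isinstance(fill, TemplateFill)
                and fill.inst_id in dropped_templates
            ):
                continue
            if rng.random() < p.p_drop_slot:
                log.append(
                    PerturbationEvent("drop_slot", inst.inst_id, slot)
                )
                continue
            if not isinstance(fill, TemplateFill) and rng.random() < p.p_swap_filler:
                fill = _swap_filler(
                    fill, inst, slot, entities, kept_entity_ids, schema, rng
                )
                log.append(PerturbationEvent("swap_filler", inst.inst_id, slot))
            fills.append((slot, fill))
        final_templates.append(replace(inst, fills=tuple(fills)))

    other = AnnotationSet(
        document=gold.document,
        annotator_id=annotator_id,
        entities=entities,
        templates=final_templates,
    )
    return SyntheticPair(gold=gold, other=other, log=log)


def _swap_filler(
    fill: Filler,
    inst: TemplateInstance,
    slot: str,
    entities: list[EntityAnnotation],
    kept_ids: set[str],
    schema: SchemaDef,
    rng: np.random.Generator,
) -> Filler:
    if isinstance(fill, LiteralFill):
        return LiteralFill(fill.value + "*")
    if isinstance(fill, EntityFill):
        current = fill.ann_id
        others = [e for e in entities if e.ann_id != current]
        if others:
            return EntityFill(others[int(rng.integers(0, len(others)))].ann_id)
        return fill
    return fill


def perturb_corpus(
    golds: Sequence[AnnotationSet],
    config: GeneratorConfig,
    schema: Optional[SchemaDef] = None,
) -> list[SyntheticPair]:
    """Perturb every document with per-document sub-seeds of config.seed."""
    children = np.random.SeedSequence(config.seed + 1).spawn(len(golds))
    return [
        perturb(
            gold,
            config,
            seed=int(child.generate_state(1)[0] % (2**31)),
            schema=schema,
        )
        for gold, child in zip(golds, children)
    ]


def gold_categories(aset: AnnotationSet) -> set[str]:
    return {e.category for e in aset.entities}


# -- rate recovery -----------------------------------------------------------


@dataclass(frozen=True)
class RateEstimates:
    p_drop_entity: float
    p_type_swap: float
    n_gold_entities: int
    warnings: tuple[str, ...] = ()


def recover_rates(
    pairs: Sequence[SyntheticPair], min_items: int = 200
) -> RateEstimates:
    """Estimate entity drop and type-confusion rates from annotated pairs.

    Gold entities are matched one-to-one to second-annotator entities by
    exact span; a gold entity with no span match (same or other category,
    and no same-category overlap) was dropped, and a span match with a
    different category is a type confusion.  The drop rate is the missing
    fraction of gold entities; the swap rate is the confusion fraction
    among the entities the second annotator produced.
    """
    n_gold = dropped = swapped = 0
    for pair in pairs:
        gold_ents = pair.gold.entities
        other = list(pair.other.entities)
        n_gold += len(gold_ents)
        consumed = [False] * len(other)
        for g in gold_ents:
            exact = next(
                (
                    i
                    for i, o in enumerate(other)
                    if not consumed[i] and (o.start, o.end) == (g.start, g.end)
                    and o.category == g.category
                ),
                None,
            )
            if exact is not None:
                consumed[exact] = True
                continue
            confused = next(
                (
                    i
                    for i, o in enumerate(other)
                    if not consumed[i] and (o.start, o.end) == (g.start, g.end)
                ),
                None,
            )
            if confused is not None:
                consumed[confused] = True
                swapped += 1
                continue
            overlap = next(
                (
                    i
                    for i, o in enumerate(other)
                    if not consumed[i]
                    and o.category == g.category
                    and o.overlaps(g)
                ),
                None,
            )
            if overlap is not None:
                consumed[overlap] = True  # boundary jitter, not a drop
            else:
                dropped += 1
    warnings: list[str] = []
    if n_gold < min_items:
        warnings.append(
            f"only {n_gold} gold entities; estimates have wide intervals"
        )
    p_drop = dropped / n_gold if n_gold else 0.0
    survivors = n_gold - dropped
    p_swap = swapped / survivors if survivors else 0.0
    return RateEstimates(
        p_drop_entity=p_drop,
        p_type_swap=p_swap,
        n_gold_entities=n_gold,
        warnings=tuple(warnings),
    )
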