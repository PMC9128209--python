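"""A worked example: the bimatoprost interventional arm of a glaucoma trial.

One arm of PubMed abstract 21034177 compares bimatoprost 0.03% once daily
against travoprost; the schematic annotation of the bimatoprost arm is an
``Arm`` instance holding an ``Intervention`` (frequency "once daily",
medication bimatoprost 0.03 %) and an ``Outcome``.  Exported to RDF this
structure yields the statements::

    data:Arm_bimatoprost          rdf:type              ctro:Arm
    data:Arm_bimatoprost          ctro:hasIntervention  data:Intervention_bimatoprost
    data:Arm_bimatoprost          ctro:hasOutcome       data:Outcome_bimatoprost
    data:Intervention_bimatoprost ctro:hasFrequency     "once daily"
    data:Intervention_bimatoprost ctro:hasMedication    data:Medication_bimatoprost
    data:Medication_bimatoprost   ctro:hasDrug          data:Bimatoprost
    data:Medication_bimatoprost   ctro:hasDoseValue     "0.03"
    data:Medication_bimatoprost   ctro:hasDoseUnit      data:Percentage
"""

from __future__ import annotations

from .model import (
    AnnotationSet,
    Document,
    IndividualFill,
    LiteralFill,
    TemplateFill,
    TemplateInstance,
)
from .rdf_io import RDF_TYPE, NamespaceConfig, Triple


def bimatoprost_arm(doc_id: str = "21034177") -> AnnotationSet:
    """The Arm/Intervention/Medication/Outcome structure described above."""
    instances = [
        TemplateInstance(
            "Arm_bimatoprost",
            "Arm",
            (
                ("hasIntervention", TemplateFill("Intervention_bimatoprost")),
                ("hasOutcome", TemplateFill("Outcome_bimatoprost")),
            ),
        ),
        TemplateInstance(
            "Intervention_bimatoprost",
            "Intervention",
            (
                ("hasFrequency", LiteralFill("once daily")),
                ("hasMedication", TemplateFill("Medication_bimatoprost")),
            ),
        ),
        TemplateInstance(
            "Medication_bimatoprost",
            "Medication",
            (
                ("hasDrug", IndividualFill("Bimatoprost")),
                ("hasDoseValue", LiteralFill("0.03")),
                ("hasDoseUnit", IndividualFill("Percentage")),
            ),
        ),
        TemplateInstance("Outcome_bimatoprost", "Outcome", ()),
    ]
    return AnnotationSet(
        document=Document(doc_id=doc_id, tokens=(), text=""),
        annotator_id="example",
        entities=[],
        templates=instances,
    )


def bimatoprost_triples(ns: NamespaceConfig = NamespaceConfig()) -> list[Triple]:
    """The eight statements listed in the module docstring."""
    d, c = ns.data_iri, ns.class_iri
    return [
        Triple(d("Arm_bimatoprost"), RDF_TYPE, c("Arm")),
        Triple(d("Arm_bimatoprost"), c("hasIntervention"), d("Intervention_bimatoprost")),
        Triple(d("Arm_bimatoprost"), c("hasOutcome"), d("Outcome_bimatoprost")),
        Triple(d("Intervention_bimatoprost"), c("hasFrequency"), "once daily", True),
        Triple(d("Intervention_bimatoprost"), c("hasMedication"), d("Medication_bimatoprost")),
        Triple(d("Medication_bimatoprost"), c("hasDrug"), d("Bimatoprost")),
        Triple(d("Medication_bimatoprost"), c("hasDoseValue"), "0.03", True),
        Triple(d("Medication_bimatoprost"), c("hasDoseUnit"), d("Percentage")),
    ]
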