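"""Corpus composition summaries.

Counts single-entity annotations (from CoNLL files) and template instances
per complex-entity type (from N-Triples files), the shape in which an
annotated clinical-trial corpus is usually summarized.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from .model import AnnotationSet


def corpus_composition(
    entity_sets: Sequence[AnnotationSet],
    template_sets: Sequence[AnnotationSet] = (),
) -> dict:
    """Document, entity and per-type template counts for a corpus."""
    per_type = Counter(
        t.template_type for aset in template_sets for t in aset.templates
    )
    return {
        "n_documents": len(
            {s.document.doc_id for s in list(entity_sets) + list(template_sets)}
        ),
        "n_single_entities": sum(len(s.entities) for s in entity_sets),
        "n_complex_entities": sum(per_type.values()),
        "complex_entities_per_type": dict(sorted(per_type.items())),
    }
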