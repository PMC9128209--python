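"""Token-level, per-category Cohen's kappa between two annotators.

For every general category *g* each annotator induces a binary marking of
the pooled corpus tokens: token *t* is marked iff some entity whose grouped
category is *g* covers *t* (overlapping spans union).  The two markings give
a 2x2 table (n11, n10, n01, n00) from which

    kappa = (P(A) - P(E)) / (1 - P(E))

with P(A) the observed agreement (n11 + n00) / N and P(E) the agreement
expected by chance from the marginal marking rates.  Categories annotated by
neither annotator are reported as absent; the corpus average is the
unweighted mean over the present categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model import AnnotationSet, pair_by_document
from .schema import SchemaDef

#: Agreement-strength bands for kappa values.
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class BinaryTokenTable:
    """2x2 marking table for one category: both / only A / only B / neither."""

    category: str
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError(f"{self.category}: negative cell count")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class KappaResult:
    category: str
    p_a: float
    p_e: float
    kappa: float
    undefined: bool = False  # chance agreement was exactly 1


@dataclass(frozen=True)
class KappaReport:
    per_category: tuple[KappaResult, ...]
    absent: tuple[str, ...]  # categories with no annotation by either side

    @property
    def average(self) -> float:
        """Unweighted mean kappa over the present categories."""
        if not self.per_category:
            raise ValueError("no categories present")
        return float(np.mean([r.kappa for r in self.per_category]))

    def result(self, category: str) -> KappaResult:
        for r in self.per_category:
            if r.category == category:
                return r
        raise KeyError(category)


def token_indicators(
    annotation_set: AnnotationSet, group: str, schema: SchemaDef
) -> np.ndarray:
    """Boolean vector: token t marked iff covered by an entity of ``group``.

    Entity categories are mapped to their general category first, so a
    *Glaucoma* span counts toward *DisorderOrSyndrome*.
    """
    if group not in schema.group_names():
        raise KeyError(f"unknown group {group!r}")
    marked = np.zeros(len(annotation_set.document), dtype=bool)
    for ent in annotation_set.entities:
        if schema.group_category(ent.category) == group:
            marked[ent.start : ent.end] = True
    return marked


def kappa_from_table(table: BinaryTokenTable) -> KappaResult:
    """Cohen's kappa from a 2x2 marking table.

    When chance agreement is exactly 1 (both marginals degenerate) kappa is
    undefined; it is then reported as 1 for identical markings and 0
    otherwise, with the ``undefined`` flag set.
    """
    n = table.n
    if n == 0:
        raise ValueError(f"{table.category}: empty table")
    p_a = (table.n11 + table.n00) / n
    p_mark_a = (table.n11 + table.n10) / n
    p_mark_b = (table.n11 + table.n01) / n
    p_e = p_mark_a * p_mark_b + (1 - p_mark_a) * (1 - p_mark_b)
    if math.isclose(p_e, 1.0):
        return KappaResult(
            category=table.category,
            p_a=p_a,
            p_e=1.0,
            kappa=1.0 if math.isclose(p_a, 1.0) else 0.0,
            undefined=True,
        )
    kappa = (p_a - p_e) / (1 - p_e)
    return KappaResult(category=table.category, p_a=p_a, p_e=p_e, kappa=kappa)


def tabulate(
    sets_a: Sequence[AnnotationSet],
    sets_b: Sequence[AnnotationSet],
    group: str,
    schema: SchemaDef,
) -> BinaryTokenTable:
    """Pool tokens corpus-wide and tabulate both annotators' markings."""
    n11 = n10 = n01 = n00 = 0
    for set_a, set_b in pair_by_document(sets_a, sets_b):
        a = token_indicators(set_a, group, schema)
        b = token_indicators(set_b, group, schema)
        n11 += int(np.sum(a & b))
        n10 += int(np.sum(a & ~b))
        n01 += int(np.sum(~a & b))
        n00 += int(np.sum(~a & ~b))
    return BinaryTokenTable(category=group, n11=n11, n10=n10, n01=n01, n00=n00)


def kappa_report(
    sets_a: Sequence[AnnotationSet],
    sets_b: Sequence[AnnotationSet],
    schema: SchemaDef,
    groups: Optional[Sequence[str]] = None,
) -> KappaReport:
    """Per-category kappa over the paired corpus, plus absent categories."""
    sets_a, sets_b = list(sets_a), list(sets_b)
    if groups is None:
        groups = schema.group_names()
    results: list[KappaResult] = []
    absent: list[str] = []
    for group in groups:
        table = tabulate(sets_a, sets_b, group, schema)
        if table.n11 + table.n10 + table.n01 == 0:
            absent.append(group)
            continue
        results.append(kappa_from_table(table))
    return KappaReport(per_category=tuple(results), absent=tuple(absent))


def classify_kappa(value: float) -> str:
    """Map a kappa value to its agreement-strength band."""
    if value > 1:
        raise ValueError(f"kappa {value} exceeds 1")
    if value < 0:
        return "none"
    for upper, label in KAPPA_BANDS:
        if value <= upper:
            return label
    return KAPPA_BANDS[-1][1]


def write_kappa_tsv(report: KappaReport, path: Union[str, Path]) -> None:
    """TSV with one row per category and a final average row.

    Absent categories are printed with a hyphen in the value columns.
    """
    lines = ["category\tp_a\tp_e\tkappa\tband"]
    rows = {r.category: r for r in report.per_category}
    for cat in sorted(set(rows) | set(report.absent)):
        if cat in rows:
            r = rows[cat]
            lines.append(
                f"{cat}\t{r.p_a:.4f}\t{r.p_e:.4f}\t{r.kappa:.4f}"
                f"\t{classify_kappa(r.kappa)}"
            )
        else:
            lines.append(f"{cat}\t-\t-\t-\t-")
    avg = report.average
    lines.append(f"Avg. Kappa\t\t\t{avg:.4f}\t{classify_kappa(avg)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
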