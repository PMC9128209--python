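"""Complex-entity agreement: pair scoring, alignment, micro-F1 bookkeeping.

The greedy aligner is checked against two independent oracles: a
step-by-step re-derivation of the greedy rule from naively computed pair
scores, and exhaustive enumeration of all one-to-one matchings (for the
optimality bound on total matched fills).
"""

import itertools
from collections import Counter

import numpy as np
import pytest

import ctroeval as ce
from ctroeval.template_agreement import (
    AlignmentError,
    MatchCounts,
    align_instances,
    f1,
    fill_match,
    pair_counts,
    pair_slot_counts,
    score_annotation_sets,
    score_corpus,
)


def _empty_ctx(doc_id="d1"):
    doc = ce.Document(doc_id, (), "")
    return ce.AnnotationSet(document=doc, annotator_id="x")


def _med(inst_id, fills):
    return ce.TemplateInstance(inst_id, "Medication", tuple(fills))


DRUG = lambda name: ce.IndividualFill(name)
LIT = lambda v: ce.LiteralFill(v)


class TestF1:
    def test_perfect_counts_score_one(self):
        assert f1(MatchCounts(tp=3)) == 1.0

    def test_no_true_positives_score_zero(self):
        assert f1(MatchCounts(tp=0, fp=2, fn=1)) == 0.0

    def test_hand_substitution(self):
        assert f1(MatchCounts(tp=2, fp=1, fn=1)) == pytest.approx(2 / 3)

    def test_all_zero_counts_are_undefined(self):
        with pytest.raises(ValueError):
            f1(MatchCounts())


class TestFillMatch:
    def test_same_individual_at_different_positions_matches(self, mini_schema):
        # the slot can be filled with any mention of the entity
        doc = ce.Document(
            "d1",
            tuple(ce.tokenize("a b c d e f")),
            "a b c d e f",
        )
        ctx_a = ce.AnnotationSet(
            document=doc,
            annotator_id="a",
            entities=[ce.EntityAnnotation("e1", "Timolol", 0, 1, "a")],
        )
        ctx_b = ce.AnnotationSet(
            document=doc,
            annotator_id="b",
            entities=[ce.EntityAnnotation("e9", "Timolol", 4, 5, "e")],
        )
        assert fill_match(
            ce.EntityFill("e1"), ce.EntityFill("e9"), ctx_a, ctx_b, mini_schema
        )

    def test_literal_values_compare_whitespace_normalized(self, mini_schema):
        ctx = _empty_ctx()
        assert fill_match(LIT("0.03"), LIT(" 0.03  "), ctx, ctx, mini_schema)

    def test_different_individuals_do_not_match(self, mini_schema):
        ctx = _empty_ctx()
        assert not fill_match(
            DRUG("Timolol"), DRUG("Latanoprost"), ctx, ctx, mini_schema
        )


class TestPairCounts:
    def test_missing_unit_gives_one_false_negative(self, mini_schema):
        ctx = _empty_ctx()
        m_a = _med(
            "MA",
            [("hasDrug", DRUG("Timolol")), ("hasDoseValue", LIT("0.5"))],
        )
        m_b = _med(
            "MB",
            [
                ("hasDrug", DRUG("Timolol")),
                ("hasDoseValue", LIT("0.5")),
                ("hasDoseUnit", DRUG("Percentage")),
            ],
        )
        counts = pair_counts(m_a, m_b, ctx, ctx, mini_schema)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 1)
        assert f1(counts) == pytest.approx(0.8)

    def test_identical_instances_have_no_errors(self, mini_schema):
        ctx = _empty_ctx()
        m = _med("M", [("hasDrug", DRUG("Timolol"))])
        counts = pair_counts(m, m, ctx, ctx, mini_schema)
        assert counts.fp == counts.fn == 0 and counts.tp == 1

    def test_disjoint_fills_have_no_true_positives(self, mini_schema):
        ctx = _empty_ctx()
        m_a = _med("MA", [("hasDrug", DRUG("Timolol"))])
        m_b = _med("MB", [("hasDrug", DRUG("Latanoprost"))])
        assert pair_counts(m_a, m_b, ctx, ctx, mini_schema).tp == 0

    def test_type_mismatch_is_an_error(self, mini_schema):
        ctx = _empty_ctx()
        arm = ce.TemplateInstance("A", "Arm", ())
        with pytest.raises(AlignmentError):
            pair_counts(_med("M", []), arm, ctx, ctx, mini_schema)


# -- independent oracles -----------------------------------------------------


def _naive_values(inst, schema):
    """Per-slot value multisets, derived directly from the fill objects."""
    out = {}
    for slot, fill in inst.fills:
        if isinstance(fill, ce.TemplateFill):
            continue
        if isinstance(fill, ce.LiteralFill):
            v = ("literal", " ".join(fill.value.split()))
        else:
            v = ("individual", fill.name)
        out.setdefault(slot, []).append(v)
    return out


def _naive_pair(inst_a, inst_b, schema):
    va, vb = _naive_values(inst_a, schema), _naive_values(inst_b, schema)
    tp = fp = fn = 0
    for slot in set(va) | set(vb):
        ca, cb = Counter(va.get(slot, [])), Counter(vb.get(slot, []))
        inter = sum((ca & cb).values())
        tp += inter
        fp += sum(ca.values()) - inter
        fn += sum(cb.values()) - inter
    if tp + fp + fn == 0:
        return 1.0, 0  # vacuous agreement
    return 2 * tp / (fp + fn + 2 * tp), tp


def greedy_oracle(list_a, list_b, schema):
    """Step-by-step application of the greedy best-first rule."""
    scores = {
        (a.inst_id, b.inst_id): _naive_pair(a, b, schema)
        for a in list_a
        for b in list_b
    }
    free_a = [a.inst_id for a in list_a]
    free_b = [b.inst_id for b in list_b]
    pairs = []
    while free_a and free_b:
        best = max(scores[(a, b)][0] for a in free_a for b in free_b)
        if best <= 0:
            break
        a, b = min(
            (a, b)
            for a in free_a
            for b in free_b
            if scores[(a, b)][0] == best
        )
        pairs.append((a, b, best))
        free_a.remove(a)
        free_b.remove(b)
    return pairs


def _random_instances(rng, side, n):
    drugs = ["Timolol", "Latanoprost", "Bimatoprost"]
    out = []
    for i in range(n):
        fills = []
        if rng.random() < 0.9:
            fills.append(("hasDrug", DRUG(drugs[rng.integers(0, 3)])))
        if rng.random() < 0.7:
            fills.append(("hasDoseValue", LIT(f"0.{rng.integers(1, 4)}")))
        if rng.random() < 0.5:
            fills.append(("hasDoseUnit", DRUG("Percentage")))
        out.append(_med(f"{side}{i}", fills))
    return out


class TestAlignment:
    def test_worse_of_two_candidates_stays_unaligned(self, mini_schema):
        ctx = _empty_ctx()
        m1 = _med("M1", [("hasDrug", DRUG("Latanoprost"))])
        m2 = _med(
            "M2",
            [("hasDrug", DRUG("Timolol")), ("hasDoseValue", LIT("0.5"))],
        )
        m3 = _med(
            "M3",
            [("hasDrug", DRUG("Timolol")), ("hasDoseValue", LIT("0.5"))],
        )
        res = align_instances([m1, m2], [m3], ctx, ctx, mini_schema)
        assert res.pairs == (("M2", "M3", 1.0),)
        assert res.unaligned_a == ("M1",)

    def test_identical_lists_pair_perfectly(self, mini_schema):
        ctx = _empty_ctx()
        insts = _random_instances(np.random.default_rng(0), "M", 3)
        res = align_instances(insts, insts, ctx, ctx, mini_schema)
        assert len(res.pairs) == 3
        assert all(s == 1.0 for _, _, s in res.pairs)

    def test_mixed_template_types_raise(self, mini_schema):
        ctx = _empty_ctx()
        with pytest.raises(AlignmentError):
            align_instances(
                [_med("M", [])],
                [ce.TemplateInstance("A", "Arm", ())],
                ctx,
                ctx,
                mini_schema,
            )

    def test_greedy_matches_oracle_and_optimal_dominates(self, mini_schema):
        # 500 random pairs of instance lists, sizes up to 3x3
        ctx = _empty_ctx()
        rng = np.random.default_rng(1234)
        for _ in range(500):
            list_a = _random_instances(rng, "A", int(rng.integers(0, 4)))
            list_b = _random_instances(rng, "B", int(rng.integers(0, 4)))
            res = align_instances(list_a, list_b, ctx, ctx, mini_schema)
            expected = greedy_oracle(list_a, list_b, mini_schema)
            assert [(a, b) for a, b, _ in res.pairs] == [
                (a, b) for a, b, _ in expected
            ]
            for got, exp in zip(res.pairs, expected):
                assert got[2] == pytest.approx(exp[2])
            # optimal assignment: total tp at least greedy's, and no worse
            # than any one-to-one matching enumerated exhaustively
            tp_of = {
                (a.inst_id, b.inst_id): pair_counts(
                    a, b, ctx, ctx, mini_schema
                ).tp
                for a in list_a
                for b in list_b
            }
            greedy_tp = sum(tp_of[(a, b)] for a, b, _ in res.pairs)
            best_tp = 0
            ids_a = [a.inst_id for a in list_a]
            ids_b = [b.inst_id for b in list_b]
            k = min(len(ids_a), len(ids_b))
            for a_subset in itertools.combinations(ids_a, k):
                for b_perm in itertools.permutations(ids_b, k):
                    best_tp = max(
                        best_tp,
                        sum(tp_of[(a, b)] for a, b in zip(a_subset, b_perm)),
                    )
            opt = align_instances(
                list_a, list_b, ctx, ctx, mini_schema, method="optimal"
            )
            opt_tp = sum(tp_of[(a, b)] for a, b, _ in opt.pairs)
            assert greedy_tp <= opt_tp == best_tp


class TestScoring:
    def test_deep_copy_scores_one_everywhere(self, mini_schema, small_gold):
        _, golds = small_gold
        for gold in golds:
            report = score_annotation_sets(gold.copy(), gold, mini_schema)
            assert report.micro_f1 == 1.0
            for counts in report.per_slot.values():
                assert counts.fp == counts.fn == 0

    def test_cross_reference_is_tp_only_if_referents_aligned(self, mini_schema):
        ctx_a = _empty_ctx()
        ctx_b = _empty_ctx()
        m1 = _med("M1", [("hasDrug", DRUG("Latanoprost"))])
        m2 = _med(
            "M2", [("hasDrug", DRUG("Timolol")), ("hasDoseValue", LIT("0.5"))]
        )
        m3 = _med(
            "M3", [("hasDrug", DRUG("Timolol")), ("hasDoseValue", LIT("0.5"))]
        )
        i_a = ce.TemplateInstance(
            "IA",
            "Intervention",
            (
                ("hasMedication", ce.TemplateFill("M1")),
                ("hasMedication", ce.TemplateFill("M2")),
            ),
        )
        i_b = ce.TemplateInstance(
            "IB", "Intervention", (("hasMedication", ce.TemplateFill("M3")),)
        )
        ctx_a.templates.extend([m1, m2, i_a])
        ctx_b.templates.extend([m3, i_b])
        report = score_annotation_sets(ctx_a, ctx_b, mini_schema)
        med_ref = report.per_slot[("Intervention", "hasMedication")]
        # M2->M3 aligned: one tp; M1 dangles: one fp
        assert (med_ref.tp, med_ref.fp, med_ref.fn) == (1, 1, 0)
        # all single-entity fills of unaligned M1 are false positives
        drug = report.per_slot[("Medication", "hasDrug")]
        assert (drug.tp, drug.fp, drug.fn) == (1, 1, 0)

    def test_document_mismatch_is_an_error(self, mini_schema):
        a = _empty_ctx("d1")
        b = _empty_ctx("d2")
        with pytest.raises(AlignmentError):
            score_annotation_sets(a, b, mini_schema)

    def test_counts_conserve_fill_totals(self, mini_schema):
        # counting oracle on perturbed synthetic pairs
        config = ce.GeneratorConfig(
            seed=77,
            n_docs=6,
            perturbation=ce.PerturbationConfig(
                p_drop_entity=0.15,
                p_drop_template=0.1,
                p_drop_slot=0.1,
                p_swap_filler=0.1,
            ),
        )
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        for pair in pairs:
            report = score_annotation_sets(pair.other, pair.gold, mini_schema)
            gold_fills = Counter(
                (t.template_type, s)
                for t in pair.gold.templates
                for s, _ in t.fills
            )
            other_fills = Counter(
                (t.template_type, s)
                for t in pair.other.templates
                for s, _ in t.fills
            )
            for key, counts in report.per_slot.items():
                assert counts.tp + counts.fn == gold_fills[key]
                assert counts.tp + counts.fp == other_fills[key]

    def test_role_swap_swaps_fp_fn_and_preserves_f1(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=7,
            n_docs=4,
            perturbation=ce.PerturbationConfig(
                p_drop_entity=0.2, p_swap_filler=0.15, p_drop_template=0.1
            ),
        )
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        fwd = score_corpus([p.other for p in pairs], golds, mini_schema)
        rev = score_corpus(golds, [p.other for p in pairs], mini_schema)
        assert fwd.micro_f1 == pytest.approx(rev.micro_f1)
        for key, counts in fwd.per_slot.items():
            assert rev.per_slot[key] == counts.swapped()

    def test_micro_f1_recomputes_from_summed_counts(self, mini_schema, small_gold):
        config, golds = small_gold
        pairs = ce.perturb_corpus(
            golds,
            ce.GeneratorConfig(
                seed=config.seed,
                n_docs=config.n_docs,
                perturbation=ce.PerturbationConfig(p_drop_slot=0.2),
            ),
            mini_schema,
        )
        report = score_corpus([p.other for p in pairs], golds, mini_schema)
        tp = sum(c.tp for c in report.per_slot.values())
        fp = sum(c.fp for c in report.per_slot.values())
        fn = sum(c.fn for c in report.per_slot.values())
        assert report.micro_f1 == pytest.approx(2 * tp / (fp + fn + 2 * tp))
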