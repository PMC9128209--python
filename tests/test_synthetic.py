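"""Synthetic corpus generator: determinism, validity, rate recovery."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

import ctroeval as ce
from ctroeval.conll import dumps_conll
from ctroeval.synthetic import GeneratorConfigError


def _binom_99(n, p):
    return binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)


class TestGenerateGold:
    def test_same_seed_gives_byte_identical_corpora(self, mini_schema):
        config = ce.GeneratorConfig(seed=21, n_docs=6)
        a = dumps_conll(ce.generate_gold(config, mini_schema))
        b = dumps_conll(ce.generate_gold(config, mini_schema))
        assert a == b

    def test_different_seeds_differ(self, mini_schema):
        a = dumps_conll(ce.generate_gold(ce.GeneratorConfig(seed=1), mini_schema))
        b = dumps_conll(ce.generate_gold(ce.GeneratorConfig(seed=2), mini_schema))
        assert a != b

    def test_document_count_honours_config(self, mini_schema):
        golds = ce.generate_gold(ce.GeneratorConfig(seed=0, n_docs=10), mini_schema)
        assert len(golds) == 10

    def test_entity_count_within_binomial_bounds(self, mini_schema):
        # ~50 expected entities: rate 0.05 over 10 docs x 100 tokens
        config = ce.GeneratorConfig(
            seed=4,
            n_docs=10,
            tokens_per_doc=(100, 100),
            entity_rate_per_category={"Timolol": 0.05},
            p_overlap=0.0,
        )
        golds = ce.generate_gold(config, mini_schema)
        observed = sum(
            sum(1 for e in g.entities if e.category == "Timolol") for g in golds
        )
        lo, hi = _binom_99(1000, 0.05)
        # template construction may add a handful of fill-on-demand spans
        assert lo <= observed <= hi + 10

    def test_overlapping_or_embedded_spans_occur(self, mini_schema):
        config = ce.GeneratorConfig(seed=8, n_docs=5, p_overlap=0.3)
        golds = ce.generate_gold(config, mini_schema)
        assert any(
            a.overlaps(b) and a.category == b.category
            for g in golds
            for a in g.entities
            for b in g.entities
            if a.ann_id < b.ann_id
        )

    def test_unknown_category_in_rates_is_a_config_error(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=0, n_docs=1, entity_rate_per_category={"NoSuchThing": 0.1}
        )
        with pytest.raises(GeneratorConfigError):
            ce.generate_gold(config, mini_schema)

    def test_rates_outside_unit_interval_are_rejected(self):
        with pytest.raises(GeneratorConfigError):
            ce.PerturbationConfig(p_drop_entity=1.5)


class TestPerturb:
    def test_zero_rates_reproduce_the_gold_exactly(self, mini_schema, small_gold):
        _, golds = small_gold
        pairs = ce.perturb_corpus(
            golds, ce.GeneratorConfig(seed=11, n_docs=len(golds)), mini_schema
        )
        for pair in pairs:
            assert pair.log == []
            assert pair.other.entities == pair.gold.entities
            assert pair.other.templates == pair.gold.templates

    def test_zero_rates_score_one_on_every_statistic(self, mini_schema, small_gold):
        config, golds = small_gold
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        others = [p.other for p in pairs]
        assert ce.kappa_report(others, golds, mini_schema).average == 1.0
        assert ce.score_corpus(others, golds, mini_schema).micro_f1 == 1.0
        assert ce.evaluate_documents(others, golds, mode="exact").micro.f1 == 1.0

    def test_every_change_is_logged(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=31,
            n_docs=3,
            perturbation=ce.PerturbationConfig(p_drop_entity=0.3),
        )
        golds = ce.generate_gold(config, mini_schema)
        for pair in ce.perturb_corpus(golds, config, mini_schema):
            n_dropped = len(pair.gold.entities) - len(pair.other.entities)
            assert n_dropped == sum(
                1 for ev in pair.log if ev.kind == "drop_entity"
            )

    def test_drop_rate_reflected_in_fn_fraction(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=19,
            n_docs=40,
            perturbation=ce.PerturbationConfig(p_drop_entity=0.5),
        )
        golds = ce.generate_gold(config, mini_schema)
        preds = [p.other for p in ce.perturb_corpus(golds, config, mini_schema)]
        report = ce.evaluate_documents(preds, golds, mode="exact")
        counts = report.summed
        n = counts.tp + counts.fn
        lo, hi = _binom_99(n, 0.5)
        assert lo <= counts.fn <= hi

    def test_boundary_jitter_hurts_exact_but_not_partial_match(self, mini_schema):
        textual = ("Precondition", "ConclusionComment", "EndPointDescription")
        config = ce.GeneratorConfig(
            seed=23,
            n_docs=10,
            p_overlap=0.0,
            perturbation=ce.PerturbationConfig(
                p_boundary_shift=1.0, boundary_categories=textual
            ),
        )
        golds = ce.generate_gold(config, mini_schema)
        preds = [p.other for p in ce.perturb_corpus(golds, config, mini_schema)]
        exact = ce.evaluate_documents(preds, golds, mode="exact")
        partial = ce.evaluate_documents(preds, golds, mode="partial")
        assert partial.micro.f1 == 1.0
        for cat in textual:
            if cat in exact.per_type:
                assert exact.per_type[cat].f1 < 1.0
        # untouched numeric-style categories keep exact F1 = 1
        assert exact.per_type["DoseValue"].f1 == 1.0

    def test_template_drop_leaves_entity_kappa_untouched(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=29,
            n_docs=8,
            perturbation=ce.PerturbationConfig(p_drop_template=0.3),
        )
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        others = [p.other for p in pairs]
        assert ce.kappa_report(others, golds, mini_schema).average == 1.0
        assert ce.score_corpus(others, golds, mini_schema).micro_f1 < 1.0

    def test_perturbed_sets_survive_serialization_round_trip(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=37,
            n_docs=4,
            perturbation=ce.PerturbationConfig(
                p_drop_entity=0.2,
                p_type_swap=0.1,
                p_boundary_shift=0.2,
                p_drop_template=0.1,
                p_drop_slot=0.1,
                p_swap_filler=0.1,
            ),
        )
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        others = [p.other for p in pairs]
        back = ce.loads_conll(dumps_conll(others), annotator_id="annotator2")
        assert sum(len(s.entities) for s in back) == sum(
            len(s.entities) for s in others
        )
        for other in others:
            triples = ce.templates_to_triples(other, mini_schema)
            rebuilt, _ = ce.triples_to_templates(triples, mini_schema)
            assert len(rebuilt.templates) == len(other.templates)


class TestRecoverRates:
    def test_zero_perturbation_recovers_zero(self, mini_schema, small_gold):
        config, golds = small_gold
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        est = ce.recover_rates(pairs)
        assert est.p_drop_entity == 0.0 and est.p_type_swap == 0.0

    def test_drop_and_swap_rates_recovered_within_tolerance(self, mini_schema):
        config = ce.GeneratorConfig(
            seed=41,
            n_docs=75,
            perturbation=ce.PerturbationConfig(
                p_drop_entity=0.2, p_type_swap=0.1
            ),
        )
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        est = ce.recover_rates(pairs)
        assert est.n_gold_entities >= 2000
        assert est.p_drop_entity == pytest.approx(0.2, abs=0.03)
        assert est.p_type_swap == pytest.approx(0.1, abs=0.03)

    def test_small_corpora_carry_a_wide_interval_warning(self, mini_schema):
        config = ce.GeneratorConfig(seed=2, n_docs=1)
        golds = ce.generate_gold(config, mini_schema)
        pairs = ce.perturb_corpus(golds, config, mini_schema)
        est = ce.recover_rates(pairs, min_items=10_000)
        assert est.warnings
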