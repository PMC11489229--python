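"""Criteria engine: predicates, the four bundled rule systems, scoring
semantics and their invariants."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lupuscrit import (
    Category,
    SLERPI_FEATURES,
    apply_criteria,
    evaluate_predicate,
    load_criteria_set,
    probability_category,
    score_count_threshold,
    score_domain_weighted,
    score_weighted_sum,
)
from lupuscrit.criteria import DefinitionError, PredicateError, RuleKind

from conftest import make_record

TOY_WEIGHTED = {
    "name": "toy",
    "rule_kind": "weighted_sum_threshold",
    "threshold": 7,
    "threshold_is_strict": True,
    "items": [
        {"item_id": "A", "predicate": "ana", "weight": 4.0},
        {"item_id": "B", "predicate": "arthritis", "weight": 3.5},
    ],
}

TOY_DOMAIN = {
    "name": "toy-domains",
    "rule_kind": "domain_weighted_threshold",
    "threshold": 10,
    "items": [
        {"item_id": "a", "predicate": "ana", "weight": 2, "domain": "D1"},
        {"item_id": "b", "predicate": "arthritis", "weight": 4, "domain": "D1"},
        {"item_id": "c", "predicate": "serositis", "weight": 6, "domain": "D2"},
    ],
}


class TestPredicates:
    @pytest.mark.parametrize(
        "expr,features,expected",
        [
            ("leucopenia or thrombocytopenia_aiha or anemia", {"leucopenia": 1}, 1),
            ("not ana", {"ana": 1}, 0),
            ("not ana", {}, 1),
            ("biopsy_proven_nephritis and (ana or anti_dsdna)",
             {"biopsy_proven_nephritis": 1, "ana": 0, "anti_dsdna": 1}, 1),
            ("biopsy_proven_nephritis and (ana or anti_dsdna)",
             {"biopsy_proven_nephritis": 1}, 0),
            ("ana and arthritis", {"ana": 1}, 0),
        ],
    )
    def test_boolean_semantics_absent_is_zero(self, expr, features, expected):
        assert evaluate_predicate(expr, make_record(**features)) == expected

    def test_truth_table_matches_python_eval(self):
        """Exhaustive three-variable truth table against Python's own
        boolean evaluation as the oracle."""
        expr = "biopsy_proven_nephritis and (ana or anti_dsdna)"
        for n, a, d in itertools.product((0, 1), repeat=3):
            rec = make_record(biopsy_proven_nephritis=n, ana=a, anti_dsdna=d)
            assert evaluate_predicate(expr, rec) == int(bool(n and (a or d)))

    def test_undeclared_feature_rejected(self):
        with pytest.raises(PredicateError, match="undeclared feature"):
            evaluate_predicate("xyz_not_a_feature", make_record())

    def test_non_boolean_syntax_rejected(self):
        with pytest.raises(PredicateError):
            evaluate_predicate("__import__('os')", make_record())


class TestDefinitions:
    def test_bundled_slerpi_anchors(self, slerpi):
        weights = {it.item_id: it.weight for it in slerpi.items}
        assert sum(w for w in weights.values() if w > 0) == 30.5
        negatives = {k: w for k, w in weights.items() if w < 0}
        assert negatives == {"ild": -1.0}
        assert weights["thrombocytopenia_aiha"] == 4.5
        assert weights["thrombocytopenia_aiha"] == max(weights.values())
        assert slerpi.threshold == 7 and slerpi.threshold_is_strict
        assert len(slerpi.items) == 14

    def test_bundled_comparators_structure(self, all_criteria):
        by_name = {c.name: c for c in all_criteria}
        acr = by_name["ACR-1997"]
        assert acr.rule_kind is RuleKind.count_threshold
        assert len(acr.items) == 11 and acr.threshold == 4 and not acr.threshold_is_strict
        slicc = by_name["SLICC-2012"]
        assert len(slicc.items) == 17
        assert slicc.min_clinical == 1 and slicc.min_immunologic == 1
        assert len(slicc.standalone) == 1
        eular = by_name["EULAR/ACR-2019"]
        assert eular.rule_kind is RuleKind.domain_weighted_threshold
        assert eular.entry == "ana" and eular.threshold == 10

    def test_unknown_feature_in_definition_rejected(self):
        bad = dict(TOY_WEIGHTED, items=[{"item_id": "x", "predicate": "XYZ", "weight": 1.0}])
        with pytest.raises(DefinitionError, match="XYZ"):
            load_criteria_set(bad)

    def test_slerpi_weight_sum_enforced(self, slerpi):
        doc = slerpi.model_dump(mode="json")
        doc["items"][0]["weight"] += 1.0  # breaks the 30.5 anchor
        with pytest.raises(DefinitionError, match="30.5"):
            load_criteria_set(doc)

    def test_minimal_toy_definition_loads(self):
        cs = load_criteria_set(TOY_WEIGHTED)
        assert len(cs.items) == 2


class TestWeightedSum:
    def test_all_absent_scores_zero(self, slerpi):
        res = score_weighted_sum(make_record(), slerpi)
        assert res.score == 0 and res.classified == 0

    def test_ild_only_scores_minus_one_not_classified(self, slerpi):
        res = score_weighted_sum(make_record(ild=1), slerpi)
        assert res.score == -1 and res.classified == 0

    def test_maximal_patient_scores_30_5(self, slerpi):
        feats = {f: 1 for f in SLERPI_FEATURES if f != "ild"}
        res = score_weighted_sum(make_record(**feats), slerpi)
        assert res.score == 30.5 and res.classified == 1
        # adding the negatively weighted feature drops the score by exactly 1
        res2 = score_weighted_sum(make_record(**feats, ild=1), slerpi)
        assert res2.score == 29.5

    def test_strict_threshold_boundary(self):
        cs = load_criteria_set(TOY_WEIGHTED)
        assert score_weighted_sum(make_record(ana=1), cs).score == 4.0
        assert score_weighted_sum(make_record(ana=1), cs).classified == 0
        full = score_weighted_sum(make_record(ana=1, arthritis=1), cs)
        assert full.score == 7.5 and full.classified == 1
        # a score of exactly 7 is below a strict threshold of 7
        exact = load_criteria_set(
            dict(TOY_WEIGHTED, items=[{"item_id": "A", "predicate": "ana", "weight": 7.0}])
        )
        assert score_weighted_sum(make_record(ana=1), exact).classified == 0

    @given(st.lists(st.booleans(), min_size=14, max_size=14))
    def test_monotonicity_adding_positive_feature(self, slerpi, flags):
        """Turning on any positive-weight feature never decreases the score."""
        feats = dict(zip(SLERPI_FEATURES, map(int, flags)))
        base = score_weighted_sum(make_record(**feats), slerpi).score
        for f in SLERPI_FEATURES:
            if f == "ild" or feats[f] == 1:
                continue
            bumped = score_weighted_sum(make_record(**{**feats, f: 1}), slerpi).score
            assert bumped >= base

    def test_probability_matches_binary_rule(self, slerpi):
        """Bundled transform places probability 50% exactly at the binary
        threshold, so classification and probability > 50 agree."""
        for feats in ({}, {"ana": 1}, {"ana": 1, "malar_rash": 1, "arthritis": 1},
                      {f: 1 for f in SLERPI_FEATURES if f != "ild"}):
            res = score_weighted_sum(make_record(**feats), slerpi)
            assert res.classified == int(res.probability_pct > 50.0)
            assert res.category is not None


class TestCountThreshold:
    def test_acr_threshold_boundary(self, all_criteria):
        acr = next(c for c in all_criteria if c.name == "ACR-1997")
        three = make_record(malar_rash=1, arthritis=1, serositis=1)
        four = make_record(malar_rash=1, arthritis=1, serositis=1, ana=1)
        assert score_count_threshold(three, acr).classified == 0
        assert score_count_threshold(four, acr).classified == 1

    def test_slicc_requires_clinical_item(self, all_criteria):
        slicc = next(c for c in all_criteria if c.name == "SLICC-2012")
        only_immunologic = make_record(
            ana=1, anti_dsdna=1, anti_sm=1, antiphospholipid=1, low_c3_c4=1
        )
        res = score_count_threshold(only_immunologic, slicc)
        assert res.score >= 4 and res.classified == 0

    def test_slicc_standalone_nephritis_rule(self, all_criteria):
        slicc = next(c for c in all_criteria if c.name == "SLICC-2012")
        rec = make_record(biopsy_proven_nephritis=1, ana=1)
        res = score_count_threshold(rec, slicc)
        assert res.score < 4 and res.classified == 1


class TestDomainWeighted:
    def test_entry_gate_blocks_maximal_record(self, all_criteria):
        eular = next(c for c in all_criteria if c.name == "EULAR/ACR-2019")
        feats = {f: 1 for f in SLERPI_FEATURES if f != "ild"}
        feats.pop("ana")
        res = score_domain_weighted(make_record(**feats), eular)
        assert res.entry_failed == 1 and res.classified == 0 and res.score == 0

    def test_domain_max_toy(self):
        cs = load_criteria_set(TOY_DOMAIN)
        res = score_domain_weighted(make_record(ana=1, arthritis=1, serositis=1), cs)
        assert res.score == 10 and res.classified == 1  # 4 + 6, not 2+4+6
        res2 = score_domain_weighted(make_record(ana=1, serositis=1), cs)
        assert res2.score == 8 and res2.classified == 0

    def test_domain_max_equals_bruteforce_enumeration(self):
        """Independent oracle: best score over all item subsets taking at
        most one item per domain, enumerated exhaustively."""
        cs = load_criteria_set(TOY_DOMAIN)
        items = cs.items
        for bits in itertools.product((0, 1), repeat=3):
            rec = make_record(**dict(zip(("ana", "arthritis", "serositis"), bits)))
            satisfied = [it for it in items if evaluate_predicate(it.predicate, rec)]
            best = 0.0
            for sub in itertools.chain.from_iterable(
                itertools.combinations(satisfied, k) for k in range(len(satisfied) + 1)
            ):
                if len({it.domain for it in sub}) == len(sub):
                    best = max(best, sum(it.weight for it in sub))
            assert score_domain_weighted(rec, cs).score == best


class TestProbabilityCategory:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (99.98, Category.definite),
            (2.12, Category.unlikely),
            (44.0, Category.likely),
            (14.999, Category.unlikely),
            (0.0, Category.unlikely),
            (15.0, Category.possible),
            (87.0, Category.definite),
            (100.0, Category.definite),
        ],
    )
    def test_ordinal_bins(self, pct, expected):
        assert probability_category(pct) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            probability_category(101.0)

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_total_mapping(self, pct):
        assert probability_category(pct) in set(Category)


class TestApplyCriteria:
    def test_empty_cohort(self, slerpi):
        assert apply_criteria([], slerpi) == []

    def test_order_preserved_and_counts(self, default_cohort, all_criteria):
        for cs in all_criteria:
            results = apply_criteria(default_cohort.records, cs)
            assert len(results) == 865
            assert [r.patient_id for r in results] == [rec.id for rec in default_cohort.records]
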