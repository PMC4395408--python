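"""Weighted chi-square voting, confusion tallies, metric identities."""

import numpy as np
import pytest

from riskminer.classify import (
    CMARClassifier,
    ConfusionMatrix,
    classify,
    evaluate,
    max_chi_square,
    metrics,
    weighted_chi2_scores,
)
from riskminer.core import NONRA, RA
from riskminer.mining import Rule, RuleSet, mine_cars

from conftest import make_db


def _ruleset(rules, n_total, class_counts):
    return RuleSet(rules, n_total, class_counts, {})


# ---------------------------------------------------------------------------
# 40-transaction fixture: 20 RA + 20 nonRA.
# Item A in 12 RA + 4 nonRA -> rule {A}=>RA  (sup 12 of 16, conf 0.75)
# Item B in  3 RA + 9 nonRA -> rule {B}=>nonRA (sup 9 of 12, conf 0.75)
# Hand evaluation of the weighted chi-square vote for a patient with {A, B}:
#   chi2({A},RA)      = 40(12*16-4*8)^2 / (16*24*20*20) = 20/3
#   maxchi2(16,20,40) = (16 - 16*20/40)^2 * 40 * e      = 80/3
#       e = 1/320 + 1/320 + 1/480 + 1/480
#   score(RA)    = (20/3)^2 / (80/3)   = 5/3   ~ 1.6667
#   chi2({B},nonRA)   = 40(9*17-3*11)^2 / (12*28*20*20) = 30/7
#   maxchi2(12,20,40) = 120/7
#   score(nonRA) = (30/7)^2 / (120/7)  = 15/14 ~ 1.0714
# -> RA wins.
# ---------------------------------------------------------------------------

def fixture_40() -> tuple:
    pairs = []
    for i in range(20):  # RA patients
        items = {"F%d" % i}
        if i < 12:
            items.add("A")
        if i < 3:
            items.add("B")
        pairs.append((items, RA))
    for i in range(20):  # non-RA patients
        items = {"G%d" % i}
        if i < 4:
            items.add("A")
        if i < 9:
            items.add("B")
        pairs.append((items, NONRA))
    db = make_db(pairs)
    rule_a = Rule(frozenset({"A"}), RA, 12, 16, 0.75, 20 / 3, 0.6)
    rule_b = Rule(frozenset({"B"}), NONRA, 9, 12, 0.75, 30 / 7, 0.45)
    rules = _ruleset([rule_a, rule_b], 40, {RA: 20, NONRA: 20})
    return db, rules


class TestClassify:
    def test_single_matching_rule_wins_outright(self):
        _, rules = fixture_40()
        assert classify({"A"}, rules) == RA
        assert classify({"B"}, rules) == NONRA

    def test_no_matching_rule_returns_default(self):
        _, rules = fixture_40()
        assert classify({"Z"}, rules, default_label=NONRA) == NONRA
        assert classify({"Z"}, rules, default_label=RA) == RA

    def test_opposing_rules_match_hand_computed_weighted_chi2(self):
        _, rules = fixture_40()
        scores = weighted_chi2_scores({"A", "B"}, rules)
        assert scores[RA] == pytest.approx(5 / 3, abs=1e-12)
        assert scores[NONRA] == pytest.approx(15 / 14, abs=1e-12)
        assert classify({"A", "B"}, rules) == RA

    def test_max_chi_square_hand_values(self):
        assert max_chi_square(16, 20, 40) == pytest.approx(80 / 3, abs=1e-12)
        assert max_chi_square(12, 20, 40) == pytest.approx(120 / 7, abs=1e-12)

    def test_max_chi_square_degenerate_margins(self):
        assert max_chi_square(0, 20, 40) == 0.0
        assert max_chi_square(40, 20, 40) == 0.0
        assert max_chi_square(16, 0, 40) == 0.0

    def test_rule_order_never_changes_label(self):
        db, rules = fixture_40()
        reversed_rules = _ruleset(
            list(reversed(rules.rules)), rules.n_total, rules.class_counts
        )
        for t in db:
            assert classify(t.items, rules) == classify(t.items, reversed_rules)

    def test_tie_goes_to_configured_label(self):
        # two mirror-image rules with identical statistics
        rule_a = Rule(frozenset({"A"}), RA, 10, 12, 10 / 12, 8.0, 0.5)
        rule_b = Rule(frozenset({"B"}), NONRA, 10, 12, 10 / 12, 8.0, 0.5)
        rules = _ruleset([rule_a, rule_b], 40, {RA: 20, NONRA: 20})
        assert classify({"A", "B"}, rules, tie_label=RA) == RA
        assert classify({"A", "B"}, rules, tie_label=NONRA) == NONRA


class TestEvaluate:
    def test_perfect_rules_on_separable_data(self, small_separable_db):
        rs = mine_cars(small_separable_db, 0.5, 0.5, 3)
        from riskminer.mining import prune

        pruned = prune(rs, small_separable_db)
        cm = evaluate(pruned, small_separable_db)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == 10 and cm.tn == 10

    def test_all_nonra_predictions(self):
        db, _ = fixture_40(), None
        db = db[0]
        empty_rules = _ruleset([], 40, {RA: 20, NONRA: 20})
        cm = evaluate(empty_rules, db, default_label=NONRA)
        assert cm.tp == 0 and cm.fn == 20 and cm.tn == 20 and cm.fp == 0

    def test_fixture_matrix_matches_manual_tally(self):
        db, rules = fixture_40()
        cm = evaluate(rules, db, default_label=NONRA)
        # manual: RA patients predicted RA iff they carry A (A wins over B);
        # plain-F patients fall to the default nonRA.
        # RA: 12 with A -> RA; 8 others -> nonRA. tp=12, fn=8
        # nonRA: 4 with A -> RA (A beats B); 5 with B only -> nonRA;
        #        11 plain -> nonRA. fp=4, tn=16
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (12, 8, 4, 16)


class TestMetrics:
    @pytest.mark.parametrize(
        "cm, sens, spec",
        [
            (ConfusionMatrix(tp=8, fn=2), 0.8, None),
            (ConfusionMatrix(tn=72, fp=28), None, 0.72),
            (ConfusionMatrix(tp=78, fn=22, tn=74, fp=26), 0.78, 0.74),
        ],
    )
    def test_values_and_absent_denominators(self, cm, sens, spec):
        m = metrics(cm)
        assert m["sensitivity"] == (pytest.approx(sens) if sens is not None else None)
        assert m["specificity"] == (pytest.approx(spec) if spec is not None else None)

    def test_invariant_under_cell_scaling(self):
        cm1 = ConfusionMatrix(tp=3, fn=1, tn=5, fp=2)
        cm9 = ConfusionMatrix(tp=27, fn=9, tn=45, fp=18)
        assert metrics(cm1) == metrics(cm9)


class TestEstimator:
    def test_fit_predict_on_separable_data(self, small_separable_db):
        X = [t.items for t in small_separable_db]
        y = [t.label for t in small_separable_db]
        clf = CMARClassifier(min_support=0.5, min_confidence=0.5)
        assert clf.fit(X, y) is clf
        assert set(clf.classes_) == {NONRA, RA}
        assert (clf.predict(X) == np.array(y, dtype=object)).all()
        assert clf.score(X, y) == 1.0

    def test_default_label_is_majority_class(self):
        pairs = [({"A"}, RA)] * 3 + [({"B"}, NONRA)] * 7
        db = make_db(pairs)
        clf = CMARClassifier(min_support=0.5, min_confidence=0.9)
        clf.fit([t.items for t in db], [t.label for t in db])
        assert clf.default_label_ == NONRA
        assert clf.predict([{"unseen"}])[0] == NONRA

    def test_decision_scores_shape_and_agreement(self, small_separable_db):
        X = [t.items for t in small_separable_db]
        y = [t.label for t in small_separable_db]
        clf = CMARClassifier(min_support=0.3, min_confidence=0.5).fit(X, y)
        scores = clf.decision_scores(X)
        assert scores.shape == (len(X), 2)

    def test_get_set_params_roundtrip(self):
        clf = CMARClassifier(min_support=0.01)
        params = clf.get_params()
        assert params["min_support"] == 0.01
        clf.set_params(min_confidence=0.7)
        assert clf.min_confidence == 0.7

    def test_rejects_empty_sample(self):
        clf = CMARClassifier()
        with pytest.raises(ValueError):
            clf.fit([set()], [RA])

    def test_works_in_sklearn_cross_validation(self, small_separable_db):
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        X = [tuple(sorted(t.items)) for t in small_separable_db]
        y = [t.label for t in small_separable_db]
        cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        scores = cross_val_score(
            CMARClassifier(min_support=0.5, min_confidence=0.5), X, y, cv=cv
        )
        assert (scores == 1.0).all()
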