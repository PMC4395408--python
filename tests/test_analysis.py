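"""Pattern metrics (conf/lift/RR/CI), chapter mapping, viewer report."""

import numpy as np
import pytest

from riskminer.analysis import (
    ICD9_CHAPTERS,
    UNMAPPED,
    chapter_distribution,
    chapter_of,
    metrics_from_counts,
    pattern_metrics,
    relative_risk_ci,
    viewer_report,
)
from riskminer.core import NONRA, RA
from riskminer.mining import Rule, RuleSet

from conftest import make_db


class TestPatternMetrics:
    def test_lift_is_one_under_independence(self):
        # item X in half of each class -> independent of the class
        pairs = [({"X", "a"}, RA)] * 5 + [({"a"}, RA)] * 5
        pairs += [({"X", "b"}, NONRA)] * 10 + [({"b"}, NONRA)] * 10
        pm = pattern_metrics({"X"}, RA, make_db(pairs))
        assert pm.lift == pytest.approx(1.0)

    def test_rr_from_group_supports(self):
        # 10% of RA vs 2% of nonRA carry the pattern
        pairs = [({"P"}, RA)] * 10 + [({"z"}, RA)] * 90
        pairs += [({"P"}, NONRA)] * 2 + [({"z"}, NONRA)] * 98
        pm = pattern_metrics({"P"}, RA, make_db(pairs))
        assert pm.sup_ra == pytest.approx(0.10)
        assert pm.sup_nonra == pytest.approx(0.02)
        assert pm.rr == pytest.approx(5.0)

    def test_absent_pattern_flagged(self):
        pairs = [({"a"}, RA)] * 3 + [({"b"}, NONRA)] * 3
        pm = pattern_metrics({"missing"}, RA, make_db(pairs))
        assert pm.conf is None and "pattern_absent" in pm.flags
        assert pm.sup_ra == 0.0 and pm.sup_nonra == 0.0

    def test_zero_other_denominator_flagged(self):
        pairs = [({"P"}, RA)] * 4 + [({"b"}, NONRA)] * 4
        pm = pattern_metrics({"P"}, RA, make_db(pairs))
        assert pm.rr is None and "rr_undefined_zero_denominator" in pm.flags

    def test_katz_ci_closed_form(self):
        # a=30/n1=100 vs b=6/n2=300 -> RR 15
        pm = metrics_from_counts({"P"}, RA, 30, 100, 6, 300)
        assert pm.rr == pytest.approx(15.0)
        lo, hi = pm.rr_ci95
        import math

        se = math.sqrt(1 / 30 - 1 / 100 + 1 / 6 - 1 / 300)
        assert lo == pytest.approx(15.0 * math.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(15.0 * math.exp(1.959963984540054 * se))
        assert lo <= 15.0 <= hi

    def test_ci_agrees_with_bootstrap(self):
        # bootstrap oracle: resample carrier indicators, 10,000 draws;
        # counts large enough for the log-normal approximation to hold
        rng = np.random.default_rng(42)
        a, n1, b, n2 = 60, 200, 30, 300
        x1 = np.zeros(n1)
        x1[:a] = 1
        x2 = np.zeros(n2)
        x2[:b] = 1
        draws = []
        for _ in range(10_000):
            r1 = x1[rng.integers(0, n1, n1)].mean()
            r2 = x2[rng.integers(0, n2, n2)].mean()
            if r2 > 0:
                draws.append(r1 / r2)
        boot_lo, boot_hi = np.percentile(draws, [2.5, 97.5])
        lo, hi = relative_risk_ci(a, n1, b, n2)
        # log-normal approximation vs bootstrap percentiles
        assert lo == pytest.approx(boot_lo, rel=0.10)
        assert hi == pytest.approx(boot_hi, rel=0.10)

    def test_agrees_with_direct_counting_on_random_dbs(self):
        from conftest import random_db

        rng = np.random.default_rng(13)
        for _ in range(20):
            db = random_db(rng, n_items=6, n_trans=30)
            items = {"I0", "I1"}
            pm = pattern_metrics(items, RA, db)
            a = sum(1 for t in db if t.label == RA and items <= t.items)
            b = sum(1 for t in db if t.label == NONRA and items <= t.items)
            n1, n2 = db.n_ra, db.n_nonra
            if a + b:
                assert pm.conf == pytest.approx(a / (a + b))
                assert pm.lift == pytest.approx(
                    (a / (a + b)) / (n1 / (n1 + n2))
                )
            assert pm.sup_ra == pytest.approx(a / n1)
            if b:
                assert pm.rr == pytest.approx((a / n1) / (b / n2))


class TestChapters:
    def test_seventeen_chapters_in_code_order(self):
        assert len(ICD9_CHAPTERS) == 17
        bounds = [(c.low, c.high) for c in ICD9_CHAPTERS]
        assert bounds[0] == (1, 139) and bounds[-1] == (800, 999)
        assert bounds == sorted(bounds)

    @pytest.mark.parametrize(
        "code, low, high",
        [
            ("714.0", 710, 739),
            ("300", 290, 319),
            ("289.9", 280, 289),
            ("001.1", 1, 139),
            ("999.9", 800, 999),
            ("630", 630, 679),
        ],
    )
    def test_code_to_chapter(self, code, low, high):
        chapter = chapter_of(code)
        assert (chapter.low, chapter.high) == (low, high)

    @pytest.mark.parametrize("code", ["V70.0", "E812.0", "", "abc"])
    def test_unmappable_codes(self, code):
        assert chapter_of(code) is UNMAPPED


def _rule(items, consequent, conf=0.8):
    return Rule(frozenset(items), consequent, 8, 10, conf, 5.0, 0.4)


class TestChapterDistribution:
    def test_all_musculoskeletal_rules(self):
        rules = RuleSet(
            [_rule({"714.0", "719.40"}, RA), _rule({"729.1"}, RA)],
            20, {RA: 10, NONRA: 10},
        )
        rows = chapter_distribution(rules)
        assert len(rows) == 17
        msk = next(r for r in rows if r.code_range == (710, 739))
        assert msk.rate_ra == 1.0
        assert all(r.rate_ra == 0.0 for r in rows if r is not msk)

    def test_rates_match_manual_tally(self):
        rules = RuleSet(
            [
                _rule({"300.00"}, RA),          # psychiatric
                _rule({"300.00", "729.1"}, RA),  # psychiatric + musculoskeletal
                _rule({"401.9"}, RA),            # circulatory
                _rule({"462"}, NONRA),           # respiratory
                _rule({"462", "530.81"}, NONRA),  # respiratory + digestive
            ],
            50, {RA: 25, NONRA: 25},
        )
        rows = {r.code_range: r for r in chapter_distribution(rules)}
        assert rows[(290, 319)].rate_ra == pytest.approx(2 / 3)
        assert rows[(710, 739)].rate_ra == pytest.approx(1 / 3)
        assert rows[(390, 459)].rate_ra == pytest.approx(1 / 3)
        assert rows[(460, 519)].rate_nonra == pytest.approx(1.0)
        assert rows[(520, 579)].rate_nonra == pytest.approx(1 / 2)

    def test_both_zero_chapter_reports_rr_zero_null_ci(self):
        rules = RuleSet([_rule({"300.00"}, RA)], 10, {RA: 5, NONRA: 5})
        rows = {r.code_range: r for r in chapter_distribution(rules)}
        empty = rows[(630, 679)]
        assert empty.rr == 0.0 and empty.ci95 is None

    def test_every_rule_contributes_to_some_bucket(self):
        rules = RuleSet(
            [_rule({"V70.0"}, RA), _rule({"300.00"}, NONRA)],
            10, {RA: 5, NONRA: 5},
        )
        rows = chapter_distribution(rules, include_unmapped=True)
        total_hits = sum(r.n_ra_rules + r.n_nonra_rules for r in rows)
        assert total_hits >= len(rules.rules)
        assert rows[-1].chapter is UNMAPPED and rows[-1].n_ra_rules == 1


class TestViewerReport:
    def test_empty_rule_set_gives_17_zeroed_chapters(self):
        db = make_db([({"a"}, RA), ({"b"}, NONRA)])
        report = viewer_report(RuleSet([], 2, {RA: 1, NONRA: 1}), db)
        assert len(report["part1"]) == 17
        assert all(row["pattern_ratio"] == 0.0 for row in report["part1"])
        assert report["part2"] == []

    def test_part1_ratios_normalised(self):
        db = make_db([({"300.00", "729.1"}, RA), ({"462"}, NONRA)])
        rules = RuleSet(
            [_rule({"300.00"}, RA), _rule({"729.1"}, RA), _rule({"462"}, NONRA)],
            2, {RA: 1, NONRA: 1},
        )
        report = viewer_report(rules, db)
        for row in report["part1"]:
            hits = row["group_distribution"]["all"]
            assert row["pattern_ratio"] == pytest.approx(hits / 3)

    def test_part2_matches_pattern_metrics(self):
        pairs = [({"300.00", "x"}, RA)] * 6 + [({"x"}, RA)] * 4
        pairs += [({"300.00"}, NONRA)] * 2 + [({"y"}, NONRA)] * 8
        db = make_db(pairs)
        rule = Rule(frozenset({"300.00"}), RA, 6, 8, 0.75, 4.0, 0.6)
        report = viewer_report(RuleSet([rule], 20, {RA: 10, NONRA: 10}), db)
        (row,) = report["part2"]
        pm = pattern_metrics({"300.00"}, RA, db)
        assert row["lift"] == pytest.approx(pm.lift)
        assert row["conf"] == 0.75
        assert row["sup_pct"] == pytest.approx(60.0)
        assert row["descriptions"] == ["Anxiety state"]

    def test_sortable_by_attribute(self):
        db = make_db([({"300.00", "462"}, RA), ({"462"}, NONRA)])
        rules = RuleSet(
            [_rule({"300.00"}, RA, conf=0.6), _rule({"462"}, NONRA, conf=0.9)],
            2, {RA: 1, NONRA: 1},
        )
        report = viewer_report(rules, db, sort_part2_by="conf")
        confs = [row["conf"] for row in report["part2"]]
        assert confs == sorted(confs, reverse=True)
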