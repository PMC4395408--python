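"""Pattern analytics: confidence, support, lift, relative risk, chapter table.

A mined risk pattern ``X => Y`` (X a set of diagnosis codes, Y a patient
class) is characterised by

* ``conf = supp(X ∪ Y) / supp(X)`` — probability of the class given the
  pattern, estimated over the whole database;
* per-class support — the fraction of each class's patients carrying every
  code of X;
* ``lift = conf / supp(Y)`` — how much more often X and Y co-occur than
  under independence (1 means independent);
* relative risk ``RR = sup_target / sup_other`` with a 95% CI from the Katz
  log method: ``exp(ln RR ± z·sqrt(1/a − 1/n1 + 1/b − 1/n2))`` where a, b
  are carrier counts and n1, n2 the class sizes.

Chapter-level aggregation buckets rules into the 17 numeric ICD-9-CM
chapters and compares per-chapter rule rates between the two classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import NONRA, RA, TransactionDB
from .vocab import code_name

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# --------------------------------------------------------------------------
# Pattern-level metrics
# --------------------------------------------------------------------------

@dataclass
class PatternMetrics:
    """Scores for one pattern ``items => target``.

    Undefined quantities (zero denominators, pattern absent) are ``None``
    and the reason is recorded in ``flags``.
    """

    pattern: frozenset[str]
    target: str
    conf: float | None
    sup_ra: float
    sup_nonra: float
    lift: float | None
    rr: float | None
    rr_ci95: tuple[float, float] | None
    flags: list[str] = field(default_factory=list)

    @property
    def sup_target(self) -> float:
        return self.sup_ra if self.target == RA else self.sup_nonra

    @property
    def sup_other(self) -> float:
        return self.sup_nonra if self.target == RA else self.sup_ra


def relative_risk_ci(
    a: float, n1: float, b: float, n2: float, z: float = Z_95
) -> tuple[float, float] | None:
    """Katz log-method CI for RR = (a/n1)/(b/n2); None if a or b is 0."""
    if a <= 0 or b <= 0:
        return None
    rr = (a / n1) / (b / n2)
    var = 1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2
    var = max(var, 0.0)
    half = z * math.sqrt(var)
    return (rr * math.exp(-half), rr * math.exp(half))


def metrics_from_counts(
    pattern: Iterable[str],
    target: str,
    a: float,
    n1: float,
    b: float,
    n2: float,
) -> PatternMetrics:
    """Build PatternMetrics from carrier counts.

    ``a`` carriers among ``n1`` target-class patients, ``b`` carriers among
    ``n2`` other-class patients. Counts may be expected (real) values when
    deriving closed-form ground truth.
    """
    flags: list[str] = []
    n = n1 + n2
    sup_t = a / n1 if n1 > 0 else 0.0
    sup_o = b / n2 if n2 > 0 else 0.0
    if n1 == 0:
        flags.append("target_class_empty")
    if n2 == 0:
        flags.append("other_class_empty")

    n_pattern = a + b
    if n_pattern > 0:
        conf = a / n_pattern
    else:
        conf = None
        flags.append("pattern_absent")

    if conf is not None and n > 0 and n1 > 0:
        lift = conf / (n1 / n)
    else:
        lift = None

    if sup_o > 0:
        rr = sup_t / sup_o
        ci = relative_risk_ci(a, n1, b, n2)
    else:
        rr = None
        ci = None
        if "pattern_absent" not in flags:
            flags.append("rr_undefined_zero_denominator")

    target_is_ra = target == RA
    return PatternMetrics(
        pattern=frozenset(pattern),
        target=target,
        conf=conf,
        sup_ra=sup_t if target_is_ra else sup_o,
        sup_nonra=sup_o if target_is_ra else sup_t,
        lift=lift,
        rr=rr,
        rr_ci95=ci,
        flags=flags,
    )


def pattern_metrics(
    items: Iterable[str], target: str, db: TransactionDB
) -> PatternMetrics:
    """Score ``items => target`` by direct counting over ``db``."""
    itemset = frozenset(items)
    other = NONRA if target == RA else RA
    a = b = n1 = n2 = 0
    for t in db:
        carrier = itemset <= t.items
        if t.label == target:
            n1 += 1
            a += carrier
        elif t.label == other:
            n2 += 1
            b += carrier
    return metrics_from_counts(itemset, target, a, n1, b, n2)


# --------------------------------------------------------------------------
# ICD-9-CM chapters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Chapter:
    low: int
    high: int
    label: str

    def contains(self, value: int) -> bool:
        return self.low <= value <= self.high


#: The 17 numeric ICD-9-CM chapters, in code order.
ICD9_CHAPTERS: tuple[Chapter, ...] = (
    Chapter(1, 139, "Infectious and parasitic"),
    Chapter(140, 239, "Neoplasm"),
    Chapter(240, 279, "Endocrine, metabolic, and immunity"),
    Chapter(280, 289, "Blood and blood-forming organs"),
    Chapter(290, 319, "Psychiatric disorders"),
    Chapter(320, 389, "Nervous system and sense organs"),
    Chapter(390, 459, "Circulatory system"),
    Chapter(460, 519, "Respiratory system"),
    Chapter(520, 579, "Digestive system"),
    Chapter(580, 629, "Genitourinary system"),
    Chapter(630, 679, "Complications of pregnancy, childbirth, and puerperium"),
    Chapter(680, 709, "Diseases of the skin and subcutaneous tissue"),
    Chapter(710, 739, "Musculoskeletal system"),
    Chapter(740, 759, "Congenital anomalies"),
    Chapter(760, 779, "Conditions prenatal period"),
    Chapter(780, 799, "Symptoms, signs"),
    Chapter(800, 999, "Injury and poisoning"),
)

UNMAPPED = Chapter(-1, -1, "Unmapped")


def chapter_of(code: str) -> Chapter:
    """Chapter whose inclusive range contains the code's integer part.

    V- and E-codes and anything non-numeric fall into the ``Unmapped``
    bucket.
    """
    head = code.strip().split(".", 1)[0]
    if not head.isdigit():
        return UNMAPPED
    value = int(head)
    for chapter in ICD9_CHAPTERS:
        if chapter.contains(value):
            return chapter
    return UNMAPPED


# --------------------------------------------------------------------------
# Chapter-level rule distribution (Risk-Pattern table)
# --------------------------------------------------------------------------

@dataclass
class ChapterRow:
    chapter: Chapter
    n_ra_rules: int
    n_nonra_rules: int
    rate_ra: float
    rate_nonra: float
    rr: float | None
    ci95: tuple[float, float] | None

    @property
    def code_range(self) -> tuple[int, int]:
        return (self.chapter.low, self.chapter.high)

    @property
    def label(self) -> str:
        return self.chapter.label


def _rules_hitting(rules, chapter: Chapter) -> list:
    return [
        r
        for r in rules
        if any(chapter_of(c) == chapter for c in r.antecedent)
    ]


def chapter_distribution(ruleset, include_unmapped: bool = False) -> list[ChapterRow]:
    """Per-chapter rule rates for each class, with RR and Katz 95% CI.

    A rule counts toward a chapter when any antecedent code falls inside
    its range; rates are fractions of that class's rule count. Chapters
    empty in both classes report rr=0 with a null CI.
    """
    ra_rules = [r for r in ruleset.rules if r.consequent == RA]
    nonra_rules = [r for r in ruleset.rules if r.consequent == NONRA]
    n1, n2 = len(ra_rules), len(nonra_rules)
    chapters: Sequence[Chapter] = ICD9_CHAPTERS
    if include_unmapped:
        chapters = (*ICD9_CHAPTERS, UNMAPPED)

    rows = []
    for chapter in chapters:
        a = len(_rules_hitting(ra_rules, chapter))
        b = len(_rules_hitting(nonra_rules, chapter))
        rate_ra = a / n1 if n1 else 0.0
        rate_nonra = b / n2 if n2 else 0.0
        if rate_ra == 0.0 and rate_nonra == 0.0:
            rr, ci = 0.0, None
        elif rate_nonra == 0.0:
            rr, ci = None, None
        else:
            rr = rate_ra / rate_nonra
            ci = relative_risk_ci(a, n1, b, n2)
        rows.append(ChapterRow(chapter, a, b, rate_ra, rate_nonra, rr, ci))
    return rows


def chapter_table_frame(rows: list[ChapterRow]):
    """Chapter table as a DataFrame mirroring the report layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "code_range": [f"{r.chapter.low:03d}-{r.chapter.high:03d}" for r in rows],
            "category": [r.label for r in rows],
            "rate_ra_pct": [100 * r.rate_ra for r in rows],
            "rate_nonra_pct": [100 * r.rate_nonra for r in rows],
            "rr": [r.rr if r.rr is not None else float("nan") for r in rows],
            "ci_low": [r.ci95[0] if r.ci95 else float("nan") for r in rows],
            "ci_high": [r.ci95[1] if r.ci95 else float("nan") for r in rows],
        }
    )


# --------------------------------------------------------------------------
# Risk Pattern Viewer report
# --------------------------------------------------------------------------

def viewer_report(
    ruleset,
    db: TransactionDB,
    sort_part2_by: str | None = None,
    descending: bool = True,
) -> dict:
    """Structured two-part report over a pruned rule set.

    Part I summarises each ICD-9-CM chapter: share of all patterns touching
    the chapter, class breakdown, and the count of distinct diseases the
    RA-class patterns use there. Part II lists every pattern with group,
    confidence, group support (%), lift, codes and descriptions; sortable
    by any numeric attribute via ``sort_part2_by``.
    """
    total = len(ruleset.rules)
    part1 = []
    for chapter in ICD9_CHAPTERS:
        hits = _rules_hitting(ruleset.rules, chapter)
        ra_hits = [r for r in hits if r.consequent == RA]
        nonra_hits = [r for r in hits if r.consequent == NONRA]
        distinct_ra_codes = {
            c for r in ra_hits for c in r.antecedent if chapter_of(c) == chapter
        }
        part1.append(
            {
                "code_range": f"{chapter.low:03d}-{chapter.high:03d}",
                "description": chapter.label,
                "pattern_ratio": len(hits) / total if total else 0.0,
                "group_distribution": {
                    "all": len(hits),
                    "RA": len(ra_hits),
                    "nonRA": len(nonra_hits),
                },
                "distinct_ra_diseases": len(distinct_ra_codes),
            }
        )

    part2 = []
    for rule in ruleset.rules:
        pm = pattern_metrics(rule.antecedent, rule.consequent, db)
        part2.append(
            {
                "group": rule.consequent,
                "conf": rule.conf,
                "sup_pct": 100 * rule.sup_group_frac,
                "lift": pm.lift,
                "chi2": rule.chi2,
                "codes": sorted(rule.antecedent),
                "descriptions": [code_name(c) for c in sorted(rule.antecedent)],
            }
        )
    if sort_part2_by is not None:
        part2.sort(
            key=lambda row: (row[sort_part2_by] is None, row[sort_part2_by]),
            reverse=descending,
        )
    return {"part1": part1, "part2": part2}
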