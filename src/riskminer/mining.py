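"""Class-association-rule mining with CMAR-style pruning.

A rule is ``P => c``: an itemset of diagnosis codes implying a patient
class. Support is *class-group-relative* — the fraction of class ``c``'s
transactions containing P — so the minimum-support threshold is applied
per class, matching how group support percentages are reported. Confidence
is ``count(P, c) / count(P)`` over the whole database.

The search is an exhaustive depth-first enumeration over per-item
transaction bitsets (equivalent to FP-growth in output: class-relative
support is anti-monotone per class, so a prefix infrequent in every class
can be pruned). Pruning follows CMAR: more-specific rules beaten by a
more-general rule of equal-or-higher confidence are dropped, rules must
pass a chi-square threshold (default 3.84, p≈0.05 at 1 d.f.), and a
database-coverage scan retires transactions after they are covered
``coverage_delta`` times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

from .core import TransactionDB


@dataclass(frozen=True)
class Rule:
    """One class association rule ``antecedent => consequent``."""

    antecedent: frozenset[str]
    consequent: str
    sup_count: int  # transactions containing antecedent AND labelled consequent
    n_antecedent: int  # transactions containing antecedent (any class)
    conf: float
    chi2: float
    sup_group_frac: float  # sup_count / size of consequent class

    def matches(self, items: frozenset[str]) -> bool:
        return self.antecedent <= items


def precedence_key(rule: Rule) -> tuple:
    """CMAR rule ordering: confidence desc, support desc, shorter, lexicographic."""
    return (-rule.conf, -rule.sup_count, len(rule.antecedent),
            tuple(sorted(rule.antecedent)))


@dataclass
class RuleSet:
    """Mined rules in precedence order plus the training-set census.

    ``class_counts`` and ``n_total`` are frozen at mining time so that
    classification never depends on test-set labels.
    """

    rules: list[Rule]
    n_total: int
    class_counts: dict[str, int]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def matching(self, items) -> list[Rule]:
        items = frozenset(items)
        return [r for r in self.rules if r.matches(items)]

    # ------------------------------------------------------------------ io
    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "n_total": self.n_total,
            "class_counts": self.class_counts,
            "rules": [
                {
                    "antecedent": sorted(r.antecedent),
                    "consequent": r.consequent,
                    "sup_count": r.sup_count,
                    "n_antecedent": r.n_antecedent,
                    "conf": r.conf,
                    "chi2": r.chi2,
                    "sup_group_frac": r.sup_group_frac,
                }
                for r in self.rules
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RuleSet":
        with open(path) as fh:
            payload = json.load(fh)
        rules = [
            Rule(
                antecedent=frozenset(r["antecedent"]),
                consequent=r["consequent"],
                sup_count=r["sup_count"],
                n_antecedent=r["n_antecedent"],
                conf=r["conf"],
                chi2=r["chi2"],
                sup_group_frac=r["sup_group_frac"],
            )
            for r in payload["rules"]
        ]
        return cls(rules, payload["n_total"], payload["class_counts"],
                   payload.get("params", {}))


# --------------------------------------------------------------------------
# chi-square
# --------------------------------------------------------------------------

def chi_square_table(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of a 2x2 table; 0 when any margin is zero."""
    n = a + b + c + d
    r1, r0 = a + b, c + d
    c1, c0 = a + c, b + d
    if min(r1, r0, c1, c0) == 0:
        return 0.0
    num = n * (a * d - b * c) ** 2
    return num / (r1 * r0 * c1 * c0)


def chi_square(rule: Rule, db: TransactionDB) -> float:
    """Chi-square of (antecedent present/absent) x (class = consequent or not)."""
    n = len(db)
    n_class = db.class_count(rule.consequent)
    a = rule.sup_count
    b = rule.n_antecedent - a
    c = n_class - a
    d = n - n_class - b
    return chi_square_table(a, b, c, d)


# --------------------------------------------------------------------------
# mining
# --------------------------------------------------------------------------

def _min_count(min_sup_frac: float, class_size: int) -> int:
    """Smallest integer count whose class fraction reaches min_sup_frac."""
    return max(1, math.ceil(min_sup_frac * class_size - 1e-9))


def mine_cars(
    db: TransactionDB,
    min_sup_frac: float,
    min_conf: float,
    max_len: int = 3,
) -> RuleSet:
    """Exhaustively mine every rule P => c meeting the thresholds.

    Returns every rule with antecedent length <= ``max_len`` whose
    class-group support fraction is >= ``min_sup_frac`` and confidence is
    >= ``min_conf``, with exact integer counts, in precedence order.
    """
    if len(db) == 0:
        raise ValueError("transaction database is empty")
    if not 0.0 < min_sup_frac <= 1.0:
        raise ValueError("min_sup_frac must be in (0, 1]")
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must be in [0, 1]")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    n = len(db)
    class_counts = db.class_counts
    labels = sorted(class_counts)
    thresholds = {c: _min_count(min_sup_frac, class_counts[c]) for c in labels}

    # per-item transaction bitsets (python ints), plus one mask per class
    item_bits: dict[str, int] = {}
    class_masks = {c: 0 for c in labels}
    for i, t in enumerate(db):
        bit = 1 << i
        class_masks[t.label] |= bit
        for item in t.items:
            item_bits[item] = item_bits.get(item, 0) | bit

    universe = sorted(item_bits)
    rules: list[Rule] = []

    def emit(itemset: tuple[str, ...], bits: int) -> None:
        total = bits.bit_count()
        for c in labels:
            count_c = (bits & class_masks[c]).bit_count()
            frac = count_c / class_counts[c]
            if count_c < thresholds[c]:
                continue
            conf = count_c / total
            if conf < min_conf:
                continue
            b = total - count_c
            cc = class_counts[c] - count_c
            dd = n - class_counts[c] - b
            rules.append(
                Rule(
                    antecedent=frozenset(itemset),
                    consequent=c,
                    sup_count=count_c,
                    n_antecedent=total,
                    conf=conf,
                    chi2=chi_square_table(count_c, b, cc, dd),
                    sup_group_frac=frac,
                )
            )

    def extend(prefix: tuple[str, ...], bits: int, start: int) -> None:
        for j in range(start, len(universe)):
            item = universe[j]
            new_bits = bits & item_bits[item] if prefix else item_bits[item]
            if new_bits == 0:
                continue
            # prune: itemset must be class-frequent in at least one class
            if not any(
                (new_bits & class_masks[c]).bit_count() >= thresholds[c]
                for c in labels
            ):
                continue
            itemset = prefix + (item,)
            emit(itemset, new_bits)
            if len(itemset) < max_len:
                extend(itemset, new_bits, j + 1)

    extend((), 0, 0)
    rules.sort(key=precedence_key)
    return RuleSet(
        rules=rules,
        n_total=n,
        class_counts=dict(class_counts),
        params={
            "min_sup_frac": min_sup_frac,
            "min_conf": min_conf,
            "max_len": max_len,
        },
    )


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------

def prune(
    ruleset: RuleSet,
    db: TransactionDB,
    chi2_threshold: float = 3.84,
    coverage_delta: int = 4,
) -> RuleSet:
    """CMAR pruning: general-rule confidence, chi-square, database coverage.

    (i) a rule is removed when a proper-subset antecedent rule with the
    same consequent has confidence >= its own (ties favour the general
    rule); (ii) rules with chi2 below ``chi2_threshold`` are removed;
    (iii) scanning survivors in precedence order, a rule is kept iff it
    matches at least one transaction not yet covered ``coverage_delta``
    times; covered transactions are retired at ``coverage_delta``.
    """
    by_key = {(r.antecedent, r.consequent): r for r in ruleset.rules}

    def beaten_by_general(rule: Rule) -> bool:
        items = sorted(rule.antecedent)
        for size in range(1, len(items)):
            for sub in combinations(items, size):
                general = by_key.get((frozenset(sub), rule.consequent))
                if general is not None and general.conf >= rule.conf:
                    return True
        return False

    survivors = [
        r
        for r in ruleset.rules
        if r.chi2 >= chi2_threshold and not beaten_by_general(r)
    ]
    survivors.sort(key=precedence_key)

    # database coverage pass over the training transactions
    item_bits: dict[str, int] = {}
    for i, t in enumerate(db):
        for item in t.items:
            item_bits[item] = item_bits.get(item, 0) | (1 << i)
    all_mask = (1 << len(db)) - 1

    cover = [0] * len(db)
    active = all_mask
    kept: list[Rule] = []
    for rule in survivors:
        bits = all_mask
        for item in rule.antecedent:
            bits &= item_bits.get(item, 0)
        live = bits & active
        if live == 0:
            continue
        kept.append(rule)
        while live:
            low = live & -live
            i = low.bit_length() - 1
            cover[i] += 1
            if cover[i] >= coverage_delta:
                active &= ~low
            live ^= low

    params = dict(ruleset.params)
    params.update({"chi2_threshold": chi2_threshold, "coverage_delta": coverage_delta})
    return RuleSet(kept, ruleset.n_total, dict(ruleset.class_counts), params)
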