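"""Independent brute-force oracles used to check the mining implementation.

Deliberately naive: powerset enumeration and direct row counting, no shared
code with the package's miner.
"""

from itertools import combinations

from riskminer.core import TransactionDB


def brute_force_rules(
    db: TransactionDB, min_sup: float, min_conf: float, max_len: int
) -> dict:
    """All rules P=>c meeting the thresholds, by direct enumeration.

    Returns {(antecedent frozenset, consequent): (sup_count, n_antecedent,
    conf)}.
    """
    universe = sorted({i for t in db for i in t.items})
    class_counts = db.class_counts
    out = {}
    for length in range(1, max_len + 1):
        for combo in combinations(universe, length):
            s = frozenset(combo)
            total = sum(1 for t in db if s <= t.items)
            if total == 0:
                continue
            for c, nc in class_counts.items():
                a = sum(1 for t in db if s <= t.items and t.label == c)
                if a == 0 or a / nc < min_sup:
                    continue
                conf = a / total
                if conf < min_conf:
                    continue
                out[(s, c)] = (a, total, conf)
    return out


def ruleset_as_dict(ruleset) -> dict:
    return {
        (r.antecedent, r.consequent): (r.sup_count, r.n_antecedent, r.conf)
        for r in ruleset.rules
    }
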