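"""Weighted chi-square associative classification (CMAR voting).

A new patient's code set is matched against the pruned rule set; matching
rules are grouped by consequent and each group is scored by

    score(c) = sum over matching rules r of  chi2(r)^2 / max_chi2(r)

where ``max_chi2`` is the largest chi-square attainable for the rule's
margins (antecedent support sup(P), class support sup(c), database size n,
all frozen from the training set):

    max_chi2 = (min(sup(P), sup(c)) - sup(P)·sup(c)/n)^2 · n · e
    e = 1/(sup(P)sup(c)) + 1/(sup(P)(n-sup(c)))
      + 1/((n-sup(P))sup(c)) + 1/((n-sup(P))(n-sup(c)))

The group with the larger score wins; patients matching no rule get the
default label (non-RA, the majority class, unless configured otherwise)
and exact ties go to RA by default — the framework is a screening aid, so
sensitivity is favoured.

:class:`CMARClassifier` wraps mining + pruning + voting as a scikit-learn
estimator over lists of code sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import NONRA, RA, Transaction, TransactionDB
from .mining import RuleSet, mine_cars, prune


def max_chi_square(sup_p: int, sup_c: int, n: int) -> float:
    """Upper bound on the 2x2 chi-square at fixed margins; 0 if degenerate."""
    if sup_p <= 0 or sup_c <= 0 or sup_p >= n or sup_c >= n:
        return 0.0
    e = (
        1.0 / (sup_p * sup_c)
        + 1.0 / (sup_p * (n - sup_c))
        + 1.0 / ((n - sup_p) * sup_c)
        + 1.0 / ((n - sup_p) * (n - sup_c))
    )
    return (min(sup_p, sup_c) - sup_p * sup_c / n) ** 2 * n * e


def weighted_chi2_scores(
    items: Iterable[str], rules: RuleSet
) -> dict[str, float]:
    """Per-class weighted chi-square score over the rules matching ``items``."""
    items = frozenset(items)
    n = rules.n_total
    scores: dict[str, float] = {}
    for rule in rules.matching(items):
        sup_c = rules.class_counts.get(rule.consequent, 0)
        bound = max_chi_square(rule.n_antecedent, sup_c, n)
        term = (rule.chi2 * rule.chi2 / bound) if bound > 0 else 0.0
        scores[rule.consequent] = scores.get(rule.consequent, 0.0) + term
    return scores


def classify(
    items: Iterable[str],
    rules: RuleSet,
    default_label: str = NONRA,
    tie_label: str = RA,
) -> str:
    """Label one code set by weighted chi-square voting.

    No matching rule -> ``default_label``; equal group scores ->
    ``tie_label``. Group sums are order-free, so permuting the rule list
    never changes the outcome.
    """
    scores = weighted_chi2_scores(items, rules)
    if not scores:
        return default_label
    best = max(scores.values())
    winners = sorted(label for label, s in scores.items() if s == best)
    if len(winners) > 1 and tie_label in winners:
        return tie_label
    return winners[0]


@dataclass
class ConfusionMatrix:
    """2x2 tally with RA as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, truth: str, predicted: str) -> None:
        if truth == RA:
            if predicted == RA:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted == RA:
                self.fp += 1
            else:
                self.tn += 1


def evaluate(
    rules: RuleSet, test: TransactionDB, default_label: str = NONRA,
    tie_label: str = RA,
) -> ConfusionMatrix:
    """Classify every test transaction and tally the confusion matrix."""
    cm = ConfusionMatrix()
    for t in test:
        cm.add(t.label, classify(t.items, rules, default_label, tie_label))
    return cm


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    An undefined ratio (empty condition-positive or -negative margin) is
    reported as None, never as 0.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    return {
        "sensitivity": cm.tp / pos if pos > 0 else None,
        "specificity": cm.tn / neg if neg > 0 else None,
    }


# --------------------------------------------------------------------------
# scikit-learn estimator
# --------------------------------------------------------------------------

class CMARClassifier(BaseEstimator, ClassifierMixin):
    """Associative classifier over diagnosis-code sets.

    Parameters
    ----------
    min_support : float
        Minimum class-group-relative support fraction for a rule (the
        production default 0.007 corresponds to 0.7%).
    min_confidence : float
        Minimum rule confidence (default 0.5).
    chi2_threshold : float
        Chi-square pruning threshold (default 3.84, p~0.05 at 1 d.f.).
    coverage_delta : int
        Database-coverage retirement count (default 4).
    max_len : int
        Maximum antecedent length (default 3).
    default_label : str or None
        Prediction when no rule matches; None means the training majority
        class.
    tie_label : str or None
        Winner on exactly tied group scores; None means RA when RA is a
        training class, else the alphabetically first class.
    do_prune : bool
        Apply CMAR pruning after mining (default True).

    Attributes
    ----------
    classes_ : ndarray of training class labels.
    rules_ : RuleSet of (pruned) mined rules in precedence order.
    default_label_, tie_label_ : resolved decision labels.
    """

    def __init__(
        self,
        min_support: float = 0.007,
        min_confidence: float = 0.5,
        chi2_threshold: float = 3.84,
        coverage_delta: int = 4,
        max_len: int = 3,
        default_label: str | None = None,
        tie_label: str | None = None,
        do_prune: bool = True,
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.chi2_threshold = chi2_threshold
        self.coverage_delta = coverage_delta
        self.max_len = max_len
        self.default_label = default_label
        self.tie_label = tie_label
        self.do_prune = do_prune

    @staticmethod
    def _as_db(X: Sequence[Iterable[str]], y: Sequence[str]) -> TransactionDB:
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        transactions = []
        for i, (items, label) in enumerate(zip(X, y)):
            itemset = frozenset(str(c) for c in items)
            if not itemset:
                raise ValueError(f"sample {i} has an empty code set")
            transactions.append(Transaction(f"x{i}", itemset, str(label)))
        return TransactionDB(transactions)

    def fit(self, X: Sequence[Iterable[str]], y: Sequence[str]) -> "CMARClassifier":
        """Mine and prune class association rules from code sets ``X``."""
        y = [str(label) for label in y]
        db = self._as_db(X, y)
        ruleset = mine_cars(db, self.min_support, self.min_confidence, self.max_len)
        if self.do_prune:
            ruleset = prune(db=db, ruleset=ruleset,
                            chi2_threshold=self.chi2_threshold,
                            coverage_delta=self.coverage_delta)
        self.rules_ = ruleset
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        counts = db.class_counts
        if self.default_label is not None:
            self.default_label_ = self.default_label
        else:
            self.default_label_ = max(sorted(counts), key=lambda c: counts[c])
        if self.tie_label is not None:
            self.tie_label_ = self.tie_label
        else:
            self.tie_label_ = RA if RA in counts else sorted(counts)[0]
        return self

    def predict(self, X: Sequence[Iterable[str]]) -> np.ndarray:
        check_is_fitted(self, "rules_")
        return np.array(
            [
                classify(items, self.rules_, self.default_label_, self.tie_label_)
                for items in X
            ],
            dtype=object,
        )

    def decision_scores(self, X: Sequence[Iterable[str]]) -> np.ndarray:
        """Weighted chi-square group scores, one column per ``classes_``."""
        check_is_fitted(self, "rules_")
        out = np.zeros((len(X), len(self.classes_)))
        for i, items in enumerate(X):
            scores = weighted_chi2_scores(items, self.rules_)
            for j, c in enumerate(self.classes_):
                out[i, j] = scores.get(c, 0.0)
        return out

    def confusion_matrix(self, X, y) -> ConfusionMatrix:
        cm = ConfusionMatrix()
        for truth, pred in zip(y, self.predict(X)):
            cm.add(str(truth), str(pred))
        return cm
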