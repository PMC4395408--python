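"""Stratified k-fold validation and parameter sweeps.

The evaluation unit is the patient transaction. Folds are stratified by
class — with a heavily imbalanced cohort an unstratified split can lose
the RA class from a fold entirely — and deterministic given the seed.

Two sweeps mirror the standard tuning procedure: the minimum-support grid
0.1%–1.1% in 0.2% steps (production choice 0.7%), and the record-count
filter grid {4, 9, 15} (production choice 15). The 'best' grid value
maximises the mean of average sensitivity and average specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import CMARClassifier, metrics
from .core import TransactionDB
from .preprocessing import PatientHistory, filter_by_record_count, to_transactions

#: Support-threshold grid: 0.1% to 1.1% at 0.2% intervals.
DEFAULT_SUPPORT_GRID = (0.001, 0.003, 0.005, 0.007, 0.009, 0.011)
#: Record-count filter grid.
DEFAULT_MIN_RECORDS_GRID = (4, 9, 15)


@dataclass
class MiningParams:
    """Thresholds for one mining + classification configuration."""

    min_sup_frac: float = 0.007
    min_conf: float = 0.5
    chi2_threshold: float = 3.84
    coverage_delta: int = 4
    max_len: int = 3
    default_label: str | None = None
    tie_label: str | None = None

    def classifier(self) -> CMARClassifier:
        return CMARClassifier(
            min_support=self.min_sup_frac,
            min_confidence=self.min_conf,
            chi2_threshold=self.chi2_threshold,
            coverage_delta=self.coverage_delta,
            max_len=self.max_len,
            default_label=self.default_label,
            tie_label=self.tie_label,
        )


@dataclass
class FoldAssignment:
    """Per-transaction fold indices for a stratified k-fold partition."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def kfold_split(db: TransactionDB, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified partition into k folds, deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = [t.label for t in db]
    counts = db.class_counts
    small = {c: n for c, n in counts.items() if n < k}
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(db), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(db)), labels)):
        assignment[test_idx] = fold
    return FoldAssignment(assignment, k, seed)


@dataclass
class CVResult:
    per_fold: list[dict]  # sensitivity, specificity, confusion matrix per fold
    avg_sensitivity: float | None
    avg_specificity: float | None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": i,
                    "sensitivity": f["sensitivity"],
                    "specificity": f["specificity"],
                }
                for i, f in enumerate(self.per_fold)
            ]
        )


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def cross_validate(
    db: TransactionDB,
    k: int = 10,
    params: MiningParams | None = None,
    seed: int = 0,
) -> CVResult:
    """Mine on k-1 folds, prune, and score the held-out fold, k times."""
    params = params or MiningParams()
    folds = kfold_split(db, k, seed)
    per_fold = []
    for fold in range(k):
        train = db.subset(folds.train_indices(fold))
        test = db.subset(folds.test_indices(fold))
        if len(train.class_counts) < len(db.class_counts):
            raise ValueError(f"fold {fold}: training split lost a class")
        clf = params.classifier()
        clf.fit([t.items for t in train], [t.label for t in train])
        cm = clf.confusion_matrix([t.items for t in test], [t.label for t in test])
        m = metrics(cm)
        per_fold.append({**m, "confusion": cm})
    return CVResult(
        per_fold=per_fold,
        avg_sensitivity=_mean_defined([f["sensitivity"] for f in per_fold]),
        avg_specificity=_mean_defined([f["specificity"] for f in per_fold]),
    )


@dataclass
class SweepResult:
    grid_value: float
    cv: CVResult

    @property
    def balanced_mean(self) -> float | None:
        vals = [self.cv.avg_sensitivity, self.cv.avg_specificity]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))


@dataclass
class SweepOutcome:
    results: list[SweepResult]
    best_value: float

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for fold, f in enumerate(r.cv.per_fold):
                rows.append(
                    {
                        "grid_value": r.grid_value,
                        "fold": fold,
                        "sensitivity": f["sensitivity"],
                        "specificity": f["specificity"],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "best_value": self.best_value,
            "grid": [
                {
                    "grid_value": r.grid_value,
                    "avg_sensitivity": r.cv.avg_sensitivity,
                    "avg_specificity": r.cv.avg_specificity,
                }
                for r in self.results
            ],
        }


def _pick_best(results: list[SweepResult]) -> float:
    best = None
    for r in results:
        score = r.balanced_mean
        if score is None:
            continue
        if best is None or score > best[0]:
            best = (score, r.grid_value)
    if best is None:
        raise ValueError("no grid value produced defined metrics")
    return best[1]


def sweep_support(
    db: TransactionDB,
    grid: Sequence[float] = DEFAULT_SUPPORT_GRID,
    k: int = 10,
    params: MiningParams | None = None,
    seed: int = 0,
) -> SweepOutcome:
    """Cross-validate at each minimum-support value on the grid."""
    if not grid:
        raise ValueError("grid is empty")
    params = params or MiningParams()
    results = []
    for value in grid:
        p = MiningParams(**{**params.__dict__, "min_sup_frac": value})
        results.append(SweepResult(value, cross_validate(db, k, p, seed)))
    return SweepOutcome(results, _pick_best(results))


def sweep_min_records(
    histories: list[PatientHistory],
    grid: Sequence[int] = DEFAULT_MIN_RECORDS_GRID,
    k: int = 10,
    params: MiningParams | None = None,
    seed: int = 0,
) -> tuple[SweepOutcome, dict[int, int]]:
    """Cross-validate after refiltering histories at each count threshold.

    Returns the sweep plus the retained-patient count per grid value.
    """
    if not grid:
        raise ValueError("grid is empty")
    params = params or MiningParams()
    results = []
    retained: dict[int, int] = {}
    for value in grid:
        kept = filter_by_record_count(histories, value)
        retained[value] = len(kept)
        db = to_transactions(kept)
        results.append(SweepResult(value, cross_validate(db, k, params, seed)))
    return SweepOutcome(results, _pick_best(results)), retained


def plot_sweep(outcome: SweepOutcome, path, xlabel: str = "grid value") -> None:
    """Line plot of average sensitivity/specificity against the grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [r.grid_value for r in outcome.results]
    sens = [r.cv.avg_sensitivity for r in outcome.results]
    spec = [r.cv.avg_specificity for r in outcome.results]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, sens, marker="o", label="avg sensitivity")
    ax.plot(xs, spec, marker="s", label="avg specificity")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("rate")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
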