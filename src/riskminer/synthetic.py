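"""Synthetic longitudinal claims with planted risk patterns.

Emulates the structure of a nationwide outpatient claims registry: two
patient classes (RA and non-RA), per-patient visit sequences inside a fixed
calendar window, at most three diagnosis codes per visit, an RA index visit
(first 714.0 diagnosis carrying the catastrophic-illness confirmation), and
configurable multi-disease patterns planted with known class-conditional
carrier probabilities. A ground-truth sidecar records class labels, index
dates, per-pattern carrier assignments and the corruption tally so every
downstream stage can be checked against exact counts.

Carrier status is drawn per patient as an independent Bernoulli at the
configured fraction, so realized carrier counts are binomial draws; the
closed-form expectations are available via :func:`expected_pattern_stats`.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import PatternMetrics, metrics_from_counts
from .core import ACODE, ICD9CM, NONRA, RA, RA_ACODE, DiagnosisRecord
from .vocab import DEFAULT_BACKGROUND_POOL

RA_INDEX_CODE = "714.0"

#: Corruption modes cycled through, each defeating one cleaning rule.
CORRUPTION_MODES = ("blank_id", "bad_sex", "birth_after_visit", "empty_code")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration cannot be realised."""


@dataclass(frozen=True)
class PlantedPattern:
    """A multi-disease pattern planted into one class at known rates."""

    items: frozenset[str]
    carrier_fraction_target: float
    carrier_fraction_other: float
    target_class: str = RA

    def __post_init__(self) -> None:
        if not self.items:
            raise ConfigurationError("planted pattern needs at least one item")
        for f in (self.carrier_fraction_target, self.carrier_fraction_other):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"carrier fraction {f} outside [0, 1]")
        if self.target_class not in (RA, NONRA):
            raise ConfigurationError(f"unknown target class {self.target_class!r}")


@dataclass(frozen=True)
class VisitCountSpec:
    """Distribution of the number of visits per patient.

    Supported: ``const`` (value), ``poisson`` (mean, min), ``uniform``
    (low, high inclusive).
    """

    name: str = "poisson"
    params: tuple[tuple[str, float], ...] = (("mean", 10.0), ("min", 2.0))

    def draw(self, rng: np.random.Generator) -> int:
        p = dict(self.params)
        if self.name == "const":
            return max(1, int(p["value"]))
        if self.name == "poisson":
            lo = int(p.get("min", 1))
            return max(lo, 1, int(rng.poisson(p["mean"])))
        if self.name == "uniform":
            return max(1, int(rng.integers(int(p["low"]), int(p["high"]) + 1)))
        raise ConfigurationError(f"unknown visit distribution {self.name!r}")


@dataclass
class CohortConfig:
    n_ra: int = 200
    n_nonra: int = 800
    date_window: tuple[dt.date, dt.date] = (dt.date(1997, 1, 1), dt.date(2008, 12, 31))
    visits_per_patient: VisitCountSpec = field(default_factory=VisitCountSpec)
    max_codes_per_visit: int = 3
    background_code_pool: Sequence[tuple[str, float]] | None = None
    planted: tuple[PlantedPattern, ...] = ()
    corruption_rate: float = 0.0
    post_index_visits: int = 0  # extra RA visits after index, to test truncation
    ra_female_fraction: float = 0.77
    nonra_female_fraction: float = 0.49
    ra_age_mean_sd: tuple[float, float] = (58.7, 15.4)
    nonra_age_mean_sd: tuple[float, float] = (42.5, 20.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ra < 0 or self.n_nonra < 0:
            raise ConfigurationError("class sizes must be non-negative")
        if self.max_codes_per_visit < 1:
            raise ConfigurationError("max_codes_per_visit must be >= 1")
        if not 0.0 <= self.corruption_rate < 1.0:
            raise ConfigurationError("corruption_rate must be in [0, 1)")
        start, end = self.date_window
        if self.n_ra > 0 and (end - start).days < 2:
            raise ConfigurationError(
                "window too short to place an RA index visit after a prior visit"
            )

    @property
    def pool(self) -> list[tuple[str, float]]:
        if self.background_code_pool is not None:
            return list(self.background_code_pool)
        return list(DEFAULT_BACKGROUND_POOL)


@dataclass
class GroundTruth:
    """Sidecar: what the generator actually did, for exact-count checks."""

    labels: dict[str, str]
    index_dates: dict[str, str]
    carriers: list[dict[str, bool]]  # one dict per planted pattern
    n_corrupted: int
    corrupted_by_mode: dict[str, int]
    n_ra: int
    n_nonra: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Cohort:
    records: list[DiagnosisRecord]
    truth: GroundTruth


def _draw_visit_dates(
    rng: np.random.Generator, start: dt.date, n_days: int, n_visits: int
) -> list[dt.date]:
    offsets = np.sort(rng.integers(0, n_days, size=n_visits))
    return [start + dt.timedelta(days=int(o)) for o in offsets]


def _birth_date(
    rng: np.random.Generator,
    first_visit: dt.date,
    age_mean_sd: tuple[float, float],
) -> dt.date:
    age = float(np.clip(rng.normal(*age_mean_sd), 18.0, 95.0))
    return first_visit - dt.timedelta(days=int(age * 365.25))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate claims rows plus the ground-truth sidecar.

    Deterministic given the config (including its seed): patients are
    generated in a fixed order from a single pseudo-random stream.
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.date_window
    span = (end - start).days

    pool_codes = np.array([c for c, _ in config.pool], dtype=object)
    weights = np.array([w for _, w in config.pool], dtype=float)
    weights = weights / weights.sum()

    labels: dict[str, str] = {}
    index_dates: dict[str, str] = {}
    carriers: list[dict[str, bool]] = [dict() for _ in config.planted]

    records: list[DiagnosisRecord] = []
    # (row index, patient) of rows eligible for corruption; index rows excluded
    corruptible: list[int] = []

    patient_specs = [(RA, i) for i in range(config.n_ra)] + [
        (NONRA, i) for i in range(config.n_nonra)
    ]
    for label, i in patient_specs:
        pid = f"{'R' if label == RA else 'N'}{i + 1:06d}"
        labels[pid] = label
        female_frac = (
            config.ra_female_fraction if label == RA else config.nonra_female_fraction
        )
        sex = "F" if rng.random() < female_frac else "M"
        n_visits = config.visits_per_patient.draw(rng)

        if label == RA:
            # index strictly inside the window, with >=1 day of history before
            index_offset = int(rng.integers(max(1, span // 4), span))
            index_date = start + dt.timedelta(days=index_offset)
            visit_dates = _draw_visit_dates(rng, start, index_offset, n_visits)
        else:
            index_date = None
            visit_dates = _draw_visit_dates(rng, start, span + 1, n_visits)

        birth = _birth_date(
            rng,
            visit_dates[0],
            config.ra_age_mean_sd if label == RA else config.nonra_age_mean_sd,
        )

        # background codes per visit, sampled without replacement within a visit
        visit_codes: list[list[str]] = []
        for _ in visit_dates:
            k = int(rng.integers(1, config.max_codes_per_visit + 1))
            k = min(k, len(pool_codes))
            codes = rng.choice(pool_codes, size=k, replace=False, p=weights)
            visit_codes.append([str(c) for c in codes])

        # plant patterns by overwriting background slots (pre-index slots only
        # for RA patients); slots never reused across patterns
        slots = [
            (vi, ci) for vi, codes in enumerate(visit_codes) for ci in range(len(codes))
        ]
        order = rng.permutation(len(slots))
        slot_iter = iter(order)
        for p_idx, pattern in enumerate(config.planted):
            frac = (
                pattern.carrier_fraction_target
                if label == pattern.target_class
                else pattern.carrier_fraction_other
            )
            is_carrier = bool(rng.random() < frac)
            carriers[p_idx][pid] = is_carrier
            if not is_carrier:
                continue
            for item in sorted(pattern.items):
                try:
                    vi, ci = slots[next(slot_iter)]
                    visit_codes[vi][ci] = item
                except StopIteration:
                    visit_codes[0].append(item)

        for vi, (vdate, codes) in enumerate(zip(visit_dates, visit_codes)):
            for code in codes:
                corruptible.append(len(records))
                records.append(
                    DiagnosisRecord(
                        patient_id=pid,
                        sex=sex,
                        birth_date=birth,
                        visit_date=vdate,
                        code=code,
                        code_system=ICD9CM,
                    )
                )

        if label == RA:
            index_dates[pid] = index_date.isoformat()
            # pre-2000 index visits carry the legacy A-code for RA
            if index_date.year < 2000:
                code, system = RA_ACODE, ACODE
            else:
                code, system = RA_INDEX_CODE, ICD9CM
            records.append(
                DiagnosisRecord(
                    patient_id=pid,
                    sex=sex,
                    birth_date=birth,
                    visit_date=index_date,
                    code=code,
                    code_system=system,
                    catastrophic_flag=True,
                )
            )
            for _ in range(config.post_index_visits):
                offset = int(rng.integers(0, max(1, span - index_offset))) + 1
                post_date = index_date + dt.timedelta(days=offset)
                if post_date > end:
                    post_date = end
                code = str(rng.choice(pool_codes, p=weights))
                corruptible.append(len(records))
                records.append(
                    DiagnosisRecord(
                        patient_id=pid,
                        sex=sex,
                        birth_date=birth,
                        visit_date=post_date,
                        code=code,
                        code_system=ICD9CM,
                    )
                )

    # corruption pass: each eligible row corrupted with prob corruption_rate,
    # cycling through the four modes so each cleaning rule is exercised
    n_corrupted = 0
    corrupted_by_mode = {m: 0 for m in CORRUPTION_MODES}
    if config.corruption_rate > 0:
        mode_i = 0
        for row_i in corruptible:
            if rng.random() >= config.corruption_rate:
                continue
            mode = CORRUPTION_MODES[mode_i % len(CORRUPTION_MODES)]
            mode_i += 1
            r = records[row_i]
            if mode == "blank_id":
                r = DiagnosisRecord("", r.sex, r.birth_date, r.visit_date, r.code,
                                    r.code_system, r.catastrophic_flag)
            elif mode == "bad_sex":
                r = DiagnosisRecord(r.patient_id, "X", r.birth_date, r.visit_date,
                                    r.code, r.code_system, r.catastrophic_flag)
            elif mode == "birth_after_visit":
                r = DiagnosisRecord(r.patient_id, r.sex,
                                    r.visit_date + dt.timedelta(days=30),
                                    r.visit_date, r.code, r.code_system,
                                    r.catastrophic_flag)
            else:  # empty_code
                r = DiagnosisRecord(r.patient_id, r.sex, r.birth_date, r.visit_date,
                                    "", r.code_system, r.catastrophic_flag)
            records[row_i] = r
            n_corrupted += 1
            corrupted_by_mode[mode] += 1

    truth = GroundTruth(
        labels=labels,
        index_dates=index_dates,
        carriers=carriers,
        n_corrupted=n_corrupted,
        corrupted_by_mode=corrupted_by_mode,
        n_ra=config.n_ra,
        n_nonra=config.n_nonra,
    )
    return Cohort(records=records, truth=truth)


def expected_pattern_stats(config: CohortConfig, pattern_index: int) -> PatternMetrics:
    """Closed-form metrics implied by a planted pattern's carrier fractions.

    Uses expected (real-valued) carrier counts ``p_target * n_target`` and
    ``p_other * n_other``; realized cohorts fluctuate binomially around
    these.
    """
    try:
        pattern = config.planted[pattern_index]
    except IndexError:
        raise IndexError(
            f"pattern index {pattern_index} out of range "
            f"({len(config.planted)} planted)"
        ) from None
    if pattern.target_class == RA:
        n1, n2 = config.n_ra, config.n_nonra
    else:
        n1, n2 = config.n_nonra, config.n_ra
    a = pattern.carrier_fraction_target * n1
    b = pattern.carrier_fraction_other * n2
    return metrics_from_counts(pattern.items, pattern.target_class, a, n1, b, n2)
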