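"""Shared containers for longitudinal diagnosis-claims mining.

The unit of raw data is one diagnosis row (patient, visit date, one code);
the unit of mining is one *transaction* per patient: the set of distinct
diagnosis codes seen in that patient's retained history, labelled RA or
non-RA.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

RA = "RA"
NONRA = "nonRA"

ICD9CM = "ICD9CM"
ACODE = "ACODE"

#: ICD-9-CM prefix that defines rheumatoid arthritis (covers 714.0x dialects).
RA_ICD9_PREFIX = "714.0"
#: Legacy Taiwanese A-code for rheumatoid arthritis (pre-2000 records).
RA_ACODE = "430"


@dataclass(frozen=True)
class DiagnosisRecord:
    """One claims row: a single diagnosis code given at one outpatient visit."""

    patient_id: str
    sex: str
    birth_date: dt.date | None
    visit_date: dt.date
    code: str
    code_system: str = ICD9CM
    catastrophic_flag: bool = False

    def is_ra_diagnosis(self) -> bool:
        """True when the code denotes rheumatoid arthritis in its code system."""
        if self.code_system == ICD9CM:
            return self.code.startswith(RA_ICD9_PREFIX)
        if self.code_system == ACODE:
            return self.code == RA_ACODE
        return False


@dataclass(frozen=True)
class Transaction:
    """A patient reduced to the set of distinct diagnosis codes in their history."""

    patient_id: str
    items: frozenset[str]
    label: str

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"transaction {self.patient_id!r} has no items")
        if self.label not in (RA, NONRA):
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class TransactionDB:
    """Class-labelled transaction database with cached class counts."""

    transactions: list[Transaction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    @property
    def n_ra(self) -> int:
        return sum(1 for t in self.transactions if t.label == RA)

    @property
    def n_nonra(self) -> int:
        return sum(1 for t in self.transactions if t.label == NONRA)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.transactions:
            counts[t.label] = counts.get(t.label, 0) + 1
        return counts

    def class_count(self, label: str) -> int:
        return self.class_counts.get(label, 0)

    def items_universe(self) -> list[str]:
        """Sorted list of every distinct code observed in the database."""
        universe: set[str] = set()
        for t in self.transactions:
            universe.update(t.items)
        return sorted(universe)

    def subset(self, indices: Iterable[int]) -> "TransactionDB":
        return TransactionDB([self.transactions[i] for i in indices])

    # ------------------------------------------------------------------ io
    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.transactions:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": t.patient_id,
                            "label": t.label,
                            "items": sorted(t.items),
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "TransactionDB":
        transactions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                transactions.append(
                    Transaction(
                        patient_id=obj["patient_id"],
                        items=frozenset(obj["items"]),
                        label=obj["label"],
                    )
                )
        return cls(transactions)


def parse_date(value: str) -> dt.date | None:
    """Parse an ISO-8601 date, returning None for blank values."""
    value = (value or "").strip()
    if not value:
        return None
    return dt.date.fromisoformat(value)
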