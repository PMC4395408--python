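"""Claims cleaning, cohort grouping and transaction construction.

The pipeline order is: ``clean`` (row-level rejection with reason codes),
``assign_groups`` (RA / non-RA labelling with index-date truncation),
``filter_by_record_count`` (drop low-information patients), and
``to_transactions`` (distinct-code itemsets per patient).

An RA case requires a qualifying first diagnosis inside the study window
(ICD-9-CM 714.0x or legacy A-code 430) *and* a catastrophic-illness
confirmation; everything on or after that index date is discarded so mined
patterns strictly precede the definite diagnosis.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass

from .core import (
    ACODE,
    ICD9CM,
    NONRA,
    RA,
    DiagnosisRecord,
    Transaction,
    TransactionDB,
)

#: Record-count filter values: the initial screen, the value physicians
#: agreed on, and the final setting used throughout.
MIN_RECORDS_PRESETS = {"initial": 4, "physician": 9, "final": 15}

_ICD9_RE = re.compile(r"^(\d{3}|V\d{2}|E\d{3})(\.\d{1,2})?$", re.IGNORECASE)
_ACODE_RE = re.compile(r"^[A-Za-z]?\d{2,4}$")

#: Rejection reasons in check order; a row gets the first failing one.
REASONS = ("id", "sex", "birth_date", "code")


def _code_malformed(record: DiagnosisRecord) -> bool:
    code = record.code.strip()
    if not code:
        return True
    if record.code_system == ICD9CM:
        return not _ICD9_RE.match(code)
    if record.code_system == ACODE:
        return not _ACODE_RE.match(code)
    return False  # unknown systems pass through; grouping ignores them


def clean(
    records: list[DiagnosisRecord],
) -> tuple[list[DiagnosisRecord], list[tuple[DiagnosisRecord, str]]]:
    """Split rows into kept and (row, reason) rejects.

    Checks, in order: blank patient ID; sex outside {F, M}; birth date
    missing or after the visit date; diagnosis code empty/malformed. The
    first failing check is the recorded reason.
    """
    kept: list[DiagnosisRecord] = []
    rejected: list[tuple[DiagnosisRecord, str]] = []
    for r in records:
        if not r.patient_id.strip():
            rejected.append((r, "id"))
        elif r.sex not in ("F", "M"):
            rejected.append((r, "sex"))
        elif r.birth_date is None or (
            r.visit_date is not None and r.birth_date > r.visit_date
        ):
            rejected.append((r, "birth_date"))
        elif _code_malformed(r):
            rejected.append((r, "code"))
        else:
            kept.append(r)
    return kept, rejected


@dataclass
class PatientHistory:
    """A patient's date-ordered retained records plus class label."""

    patient_id: str
    sex: str
    birth_date: dt.date | None
    records: list[DiagnosisRecord]
    label: str
    index_date: dt.date | None = None

    @property
    def n_records(self) -> int:
        return len(self.records)


def assign_groups(
    records: list[DiagnosisRecord],
    window: tuple[dt.date, dt.date] = (dt.date(1997, 1, 1), dt.date(2008, 12, 31)),
) -> list[PatientHistory]:
    """Label patients RA / non-RA and truncate RA histories at the index date.

    RA requires (i) an in-window record with ICD-9-CM code 714.0x or A-code
    430 and (ii) a catastrophic-illness confirmation on some record. The
    index date is the earliest qualifying diagnosis; only strictly earlier
    records are retained. Non-RA patients keep their full history.
    """
    start, end = window
    by_patient: dict[str, list[DiagnosisRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    histories = []
    for pid, rows in by_patient.items():
        rows = sorted(rows, key=lambda r: r.visit_date)
        has_flag = any(r.catastrophic_flag for r in rows)
        qualifying = [
            r
            for r in rows
            if r.is_ra_diagnosis() and start <= r.visit_date <= end
        ]
        if qualifying and has_flag:
            index_date = min(r.visit_date for r in qualifying)
            retained = [r for r in rows if r.visit_date < index_date]
            histories.append(
                PatientHistory(pid, rows[0].sex, rows[0].birth_date, retained, RA,
                               index_date)
            )
        else:
            histories.append(
                PatientHistory(pid, rows[0].sex, rows[0].birth_date, rows, NONRA)
            )
    return histories


def filter_by_record_count(
    histories: list[PatientHistory], min_records: int = MIN_RECORDS_PRESETS["final"]
) -> list[PatientHistory]:
    """Keep histories with at least ``min_records`` retained diagnosis rows.

    'Fewer than' is strict: a history with exactly ``min_records`` rows
    survives.
    """
    if min_records < 0:
        raise ValueError("min_records must be >= 0")
    return [h for h in histories if h.n_records >= min_records]


def to_transactions(histories: list[PatientHistory]) -> TransactionDB:
    """One transaction per history: the set of distinct retained codes.

    Multiplicity is discarded. Histories with no retained records carry no
    information and are skipped (the record-count filter removes them in
    the standard pipeline anyway).
    """
    transactions = []
    for h in histories:
        items = frozenset(r.code for r in h.records)
        if not items:
            continue
        transactions.append(Transaction(h.patient_id, items, h.label))
    return TransactionDB(transactions)
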