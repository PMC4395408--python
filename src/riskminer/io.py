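"""Reading and writing the delimited claims format.

One :class:`~riskminer.core.DiagnosisRecord` per row, header
``patient_id,sex,birth_date,visit_date,code,code_system,catastrophic_flag``,
ISO-8601 dates. Deliberately tolerant on read: blank fields survive so the
cleaning stage can reject them with a reason code.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .core import DiagnosisRecord, parse_date

CLAIMS_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "visit_date",
    "code",
    "code_system",
    "catastrophic_flag",
]


def records_to_frame(records: Iterable[DiagnosisRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "birth_date": r.birth_date.isoformat() if r.birth_date else "",
            "visit_date": r.visit_date.isoformat(),
            "code": r.code,
            "code_system": r.code_system,
            "catastrophic_flag": r.catastrophic_flag,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def write_claims_csv(records: Iterable[DiagnosisRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_claims_csv(path) -> list[DiagnosisRecord]:
    frame = pd.read_csv(
        path,
        dtype={"patient_id": str, "sex": str, "code": str, "code_system": str},
        keep_default_na=False,
    )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DiagnosisRecord(
                patient_id=str(row.patient_id),
                sex=str(row.sex),
                birth_date=parse_date(str(row.birth_date)),
                visit_date=parse_date(str(row.visit_date)),
                code=str(row.code),
                code_system=str(row.code_system),
                catastrophic_flag=str(row.catastrophic_flag).strip().lower()
                in ("true", "1"),
            )
        )
    return records
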