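"""PubMed literature-novelty typing for mined risk patterns.

For a pattern ``{d1, ..., dn} => target`` the joint query
``d1[TIAB] AND ... AND dn[TIAB] AND target[TIAB]`` counts publications
mentioning every disease of the pattern together with the target disease
in title/abstract. Patterns whose joint count is at or below a threshold
(default 0: never reported) are labelled Type II (novel); the rest are
Type I (established). Per-disease counts (each disease AND target) are
recorded alongside for the report.

Citation counts come through a one-method client protocol so tests run
against a fixture table; the live NCBI E-utilities client is optional and
never exercised offline.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass
from typing import Protocol, Sequence

from .vocab import code_name

TYPE_I = "TypeI"
TYPE_II = "TypeII"


def build_query(diseases: Sequence[str], target: str) -> str:
    """Conjunction [TIAB] query, original casing preserved."""
    if not diseases:
        raise ValueError("disease list is empty")
    terms = [*diseases, target]
    for term in terms:
        if not str(term).strip():
            raise ValueError("blank disease name in query")
    return " AND ".join(f"{term}[TIAB]" for term in terms)


class CountClient(Protocol):
    def count(self, query: str) -> int:  # pragma: no cover - protocol
        ...


class FixtureClient:
    """Offline client backed by a query -> count table (dict or CSV file)."""

    def __init__(self, table: dict[str, int] | None = None, path=None):
        self.table: dict[str, int] = dict(table or {})
        if path is not None:
            with open(path, newline="") as fh:
                for row in csv.DictReader(fh):
                    self.table[row["query"]] = int(row["count"])

    def count(self, query: str) -> int:
        if query not in self.table:
            raise LookupError(f"fixture has no count for query: {query}")
        return self.table[query]


class EntrezClient:
    """Live NCBI E-utilities client (esearch result count), rate limited.

    Requires biopython and network access; intended for interactive use
    only.
    """

    def __init__(self, email: str, api_key: str | None = None,
                 min_interval: float = 0.34):
        from Bio import Entrez  # deferred: optional dependency

        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self._entrez = Entrez
        self._min_interval = min_interval
        self._last = 0.0

    def count(self, query: str) -> int:
        wait = self._min_interval - (time.monotonic() - self._last)
        if wait > 0:
            time.sleep(wait)
        handle = self._entrez.esearch(db="pubmed", term=query, retmax=0)
        record = self._entrez.read(handle)
        handle.close()
        self._last = time.monotonic()
        return int(record["Count"])


@dataclass
class LiteratureResult:
    pattern: tuple[str, ...]  # disease names, in query order
    target: str
    single_disease_counts: list[int]
    joint_count: int
    novelty_type: str


def _counted(client: CountClient, query: str, retries: int = 1) -> int:
    last_err: Exception | None = None
    for _ in range(retries + 1):
        try:
            return client.count(query)
        except Exception as err:  # retry-then-error with the query attached
            last_err = err
    raise RuntimeError(f"literature count failed for query: {query}") from last_err


def assess_novelty(
    diseases: Sequence[str],
    target: str,
    client: CountClient,
    threshold: int = 0,
    retries: int = 1,
) -> LiteratureResult:
    """Type a pattern by its joint PubMed citation count.

    ``novelty_type`` is Type II iff the joint count is <= ``threshold``.
    """
    joint = _counted(client, build_query(diseases, target), retries)
    singles = [
        _counted(client, build_query([d], target), retries) for d in diseases
    ]
    return LiteratureResult(
        pattern=tuple(diseases),
        target=target,
        single_disease_counts=singles,
        joint_count=joint,
        novelty_type=TYPE_II if joint <= threshold else TYPE_I,
    )


def assess_rule_novelty(
    rule, target_name: str, client: CountClient, threshold: int = 0
) -> LiteratureResult:
    """Assess a mined rule, translating codes to disease names."""
    names = [code_name(c) for c in sorted(rule.antecedent)]
    return assess_novelty(names, target_name, client, threshold)
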