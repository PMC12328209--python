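"""Thin live HTTP adapters for the knowledge-source contract.

These talk to the real public enrichment services via the standard
library (no third-party HTTP client) and are intentionally minimal:
retries with exponential backoff, a token-bucket rate limit, and the
same :class:`~veriset.sources.KnowledgeSource` surface the fixture
implementations satisfy. They are never exercised by the offline test
suite; all behavioral guarantees are stated against the contract.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.request
from typing import Sequence

from .sources import KnowledgeSource, RetrievalError, SourceDescriptor
from .types import EvidenceItem, RetrievedTerm

GPROFILER_URL = "https://biit.cs.ut.ee/gprofiler/api/gost/profile/"
ENRICHR_ADD_URL = "https://maayanlab.cloud/Enrichr/addList"
ENRICHR_ENRICH_URL = "https://maayanlab.cloud/Enrichr/enrich"


class _TokenBucket:
    """Polite-use rate limit, default 3 requests/s per endpoint."""

    def __init__(self, rate: float = 3.0):
        self.rate = rate
        self._last = 0.0

    def wait(self) -> None:
        now = time.monotonic()
        earliest = self._last + 1.0 / self.rate
        if now < earliest:
            time.sleep(earliest - now)
        self._last = time.monotonic()


def _request(url: str, data: bytes | None = None, headers: dict | None = None,
             retries: int = 3) -> bytes:
    delay = 1.0
    last: Exception | None = None
    for _ in range(retries):
        try:
            req = urllib.request.Request(url, data=data, headers=headers or {})
            with urllib.request.urlopen(req, timeout=30) as resp:
                return resp.read()
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            last = exc
            time.sleep(delay)
            delay *= 2
    raise RetrievalError(f"transport failure for {url}: {last}")


class GProfilerLiveSource(KnowledgeSource):
    """g:GOSt over-representation query; top terms pooled over databases."""

    def __init__(self, descriptor: SourceDescriptor, organism: str = "hsapiens"):
        super().__init__(descriptor)
        self.organism = organism
        self._bucket = _TokenBucket()

    def restricted(self, databases: list[str]) -> "GProfilerLiveSource":
        desc = self.descriptor.model_copy(update={"databases": databases})
        return GProfilerLiveSource(desc, self.organism)

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        self._bucket.wait()
        self.transport_calls += 1
        payload = json.dumps(
            {"organism": self.organism, "query": list(genes)}
        ).encode()
        body = _request(
            GPROFILER_URL, payload, {"Content-Type": "application/json"}
        )
        rows = json.loads(body).get("result", [])
        rows.sort(key=lambda r: r.get("p_value", 1.0))
        kept = rows[: self.descriptor.rank_limit]
        used = []
        for r in kept:
            src = r.get("source", "")
            if src not in used:
                used.append(src)
        return EvidenceItem(
            source_id=self.source_id,
            database_name=",".join(used),
            query_genes=list(genes),
            retrieved_terms=[
                RetrievedTerm(
                    term=r.get("name", ""),
                    description=r.get("description"),
                    score=r.get("p_value"),
                )
                for r in kept
            ],
            retrieved_at_rank_limit=self.descriptor.rank_limit,
        )


class EnrichrLiveSource(KnowledgeSource):
    """Enrichr pathway query over the configured gene-set libraries."""

    def __init__(self, descriptor: SourceDescriptor):
        super().__init__(descriptor)
        self._bucket = _TokenBucket()

    def restricted(self, databases: list[str]) -> "EnrichrLiveSource":
        return EnrichrLiveSource(
            self.descriptor.model_copy(update={"databases": databases})
        )

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        self._bucket.wait()
        self.transport_calls += 1
        payload = (
            f"list={'%0A'.join(genes)}&description=veriset".encode()
        )
        body = _request(
            ENRICHR_ADD_URL, payload,
            {"Content-Type": "application/x-www-form-urlencoded"},
        )
        user_list_id = json.loads(body)["userListId"]
        pooled: list[tuple[float, str, str]] = []
        for db in self.descriptor.databases:
            self._bucket.wait()
            body = _request(
                f"{ENRICHR_ENRICH_URL}?userListId={user_list_id}"
                f"&backgroundType={db}"
            )
            for row in json.loads(body).get(db, []):
                # Enrichr row: rank, term, p-value, ...
                pooled.append((float(row[2]), str(row[1]), db))
        pooled.sort(key=lambda t: t[0])
        kept = pooled[: self.descriptor.rank_limit]
        used = []
        for _, _, db in kept:
            if db not in used:
                used.append(db)
        return EvidenceItem(
            source_id=self.source_id,
            database_name=",".join(used),
            query_genes=list(genes),
            retrieved_terms=[
                RetrievedTerm(term=t, score=p) for p, t, _ in kept
            ],
            retrieved_at_rank_limit=self.descriptor.rank_limit,
        )
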