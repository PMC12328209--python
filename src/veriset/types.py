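"""Domain types shared by every module.

A gene set ``D = {g_1 .. g_N}`` enters the pipeline, receives a process
name ``P`` and analytical narrative ``A`` at three stages (initial,
modified, final), and every affirmative claim extracted along the way is
verified against curated knowledge sources, yielding a
:class:`VerificationReport` per stage.  These types carry no computation
beyond validation and serialization.
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

SCHEMA_VERSION = "1.0"


class Stage(str, Enum):
    initial = "initial"
    modified = "modified"
    final = "final"


class SetSource(str, Enum):
    """Origin tag of a gene set; drives the masking strategy."""

    GO = "GO"
    NeST = "NeST"
    MSigDB = "MSigDB"
    custom = "custom"


class ClaimOrigin(str, Enum):
    process_name = "process_name"
    narrative = "narrative"


class DecisionCategory(str, Enum):
    supported = "supported"
    partially_supported = "partially_supported"
    refuted = "refuted"
    unknown = "unknown"
    unverified = "unverified"


class GeneSetError(ValueError):
    """Raised when a parsed record cannot form a valid gene set."""


class GeneSet(BaseModel):
    """An input gene set with an optional curated ground-truth name.

    Gene symbols are stored verbatim (human symbols are upper-case, mouse
    symbols title-case) but always compared case-insensitively.
    """

    set_id: str
    genes: list[str]
    ground_truth: Optional[str] = None
    source: SetSource = SetSource.custom
    species: str = "human"

    @field_validator("genes")
    @classmethod
    def _non_empty_no_casefold_dups(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("gene list must be non-empty")
        seen = set()
        for g in v:
            key = g.casefold()
            if key in seen:
                raise ValueError(f"duplicate gene symbol after case-folding: {g!r}")
            seen.add(key)
        return v

    def contains(self, symbol: str) -> bool:
        return symbol.casefold() in {g.casefold() for g in self.genes}


def validate_gene_set(raw: dict) -> GeneSet:
    """Build a :class:`GeneSet` from a parsed record.

    Symbols are whitespace-trimmed and de-duplicated case-insensitively,
    keeping the first occurrence.  An empty gene list is rejected with the
    offending set id named.
    """
    set_id = str(raw.get("id") or raw.get("set_id") or "").strip()
    if not set_id:
        raise GeneSetError("record has no set id")
    genes_in = [str(g).strip() for g in raw.get("genes", [])]
    genes_in = [g for g in genes_in if g]
    seen: set[str] = set()
    genes: list[str] = []
    for g in genes_in:
        key = g.casefold()
        if key not in seen:
            seen.add(key)
            genes.append(g)
    if not genes:
        raise GeneSetError(f"gene set {set_id!r} has an empty gene list")
    return GeneSet(
        set_id=set_id,
        genes=genes,
        ground_truth=raw.get("ground_truth"),
        source=raw.get("source", SetSource.custom),
        species=raw.get("species", "human"),
    )


class ProcessName(BaseModel):
    """A short biological-process name for a gene set at a given stage."""

    text: str
    stage: Stage

    @field_validator("text")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("process name must be non-empty")
        return v


class Narrative(BaseModel):
    """Multi-paragraph analytical text explaining the genes' functions."""

    text: str
    stage: Stage


class Claim(BaseModel):
    """An affirmative sentence linking gene symbols to a function phrase.

    ``claim_id`` is a deterministic digest of (origin, raw_text) so that
    reruns are diffable.  ``genes`` may be empty only when symbol
    extraction failed; such claims are later marked unverified.
    """

    claim_id: str
    genes: list[str]
    function_phrase: str
    origin: ClaimOrigin
    raw_text: str

    @field_validator("raw_text")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("claim raw_text must be non-empty")
        return v

    @classmethod
    def create(
        cls,
        genes: Iterable[str],
        function_phrase: str,
        origin: ClaimOrigin,
        raw_text: str,
    ) -> "Claim":
        digest = hashlib.sha256(f"{origin.value}|{raw_text}".encode()).hexdigest()[:16]
        return cls(
            claim_id=digest,
            genes=list(genes),
            function_phrase=function_phrase,
            origin=origin,
            raw_text=raw_text,
        )


class RetrievedTerm(BaseModel):
    term: str
    description: Optional[str] = None
    score: Optional[float] = None


class EvidenceItem(BaseModel):
    """Ranked terms one knowledge source returned for a claim's genes.

    ``database_name`` lists the backend databases that contributed terms
    (comma-joined when a source pools several), so masking soundness can
    be audited per (source, database) pair.
    """

    source_id: str
    database_name: str
    query_genes: list[str]
    retrieved_terms: list[RetrievedTerm]
    retrieved_at_rank_limit: int

    @model_validator(mode="after")
    def _within_rank_limit(self) -> "EvidenceItem":
        if len(self.retrieved_terms) > self.retrieved_at_rank_limit:
            raise ValueError(
                f"{len(self.retrieved_terms)} terms exceed rank limit "
                f"{self.retrieved_at_rank_limit} for {self.source_id}"
            )
        return self

    def databases(self) -> list[str]:
        return [d for d in self.database_name.split(",") if d]


class Decision(BaseModel):
    category: DecisionCategory
    rationale: str = ""


class ReportEntry(BaseModel):
    claim: Claim
    evidence: list[EvidenceItem]
    decision: Decision


class VerificationReport(BaseModel):
    """Per-claim evidence and decisions for one pipeline stage."""

    target_stage: ClaimOrigin
    entries: list[ReportEntry]

    def decisions(self) -> list[DecisionCategory]:
        return [e.decision.category for e in self.entries]

    def all_supported(self) -> bool:
        return bool(self.entries) and all(
            e.decision.category is DecisionCategory.supported for e in self.entries
        )

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps(e.model_dump(mode="json"), sort_keys=False)
            for e in self.entries
        )


class CallRecord(BaseModel):
    backend_id: str
    request_digest: str
    response_digest: str


class PipelineResult(BaseModel):
    """Full trace of one pipeline run: both reports, all three stages."""

    schema_version: str = SCHEMA_VERSION
    gene_set_id: str
    p_initial: ProcessName
    a_initial: Narrative
    report_p: VerificationReport
    p_modified: ProcessName
    a_modified: Narrative
    report_a: VerificationReport
    p_final: ProcessName
    a_final: Narrative
    call_log: list[CallRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _verified_twice(self) -> "PipelineResult":
        if self.report_p.target_stage is not ClaimOrigin.process_name:
            raise ValueError("report_p must target the process name")
        if self.report_a.target_stage is not ClaimOrigin.narrative:
            raise ValueError("report_a must target the narrative")
        return self

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json(indent=None).encode()).hexdigest()
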