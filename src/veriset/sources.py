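"""Knowledge-source adapters: enrichment and gene-centric Web-API
families plus offline fixture equivalents, with masking and caching.

Four source families are configured: two enrichment services (a
g:Profiler-style multi-database over-representation service and an
Enrichr-style pathway service, rank limit 5) and two gene-centric
services (NCBI E-utilities Gene/PubMed summaries and a custom
gene-centric service over gene-disease / domain / PPI / complex tables,
rank limit 10).  A masking strategy prevents a dataset's own curation
source from trivially verifying its gene sets: GO-derived sets never see
the g:Profiler service, and MSigDB-derived sets never see the
MSigDB_Hallmark_2020 database inside the Enrichr service.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, model_validator

from .types import EvidenceItem, GeneSet, RetrievedTerm, SetSource

GPROFILER_DATABASES = [
    "GO",
    "KEGG",
    "Reactome",
    "WikiPathways",
    "Transfac",
    "miRTarBase",
    "CORUM",
    "Human Phenotype Ontology",
]
ENRICHR_DATABASES = [
    "KEGG_2021_Human",
    "Reactome_2022",
    "BioPlanet_2019",
    "MSigDB_Hallmark_2020",
]
EUTILS_DATABASES = ["gene", "pubmed"]
AGENTAPI_DATABASES = ["disease", "domain", "ppi", "complex"]

ENRICHMENT_SOURCES = ("gprofiler", "enrichr")
GENE_CENTRIC_SOURCES = ("eutils", "agentapi")

_RANK_LIMITS = {"gprofiler": 5, "enrichr": 5, "eutils": 10, "agentapi": 10}


class RetrievalError(RuntimeError):
    """Typed transport/backend failure; callers degrade gracefully."""


class SourceDescriptor(BaseModel):
    source_id: str
    databases: list[str]
    rank_limit: int
    endpoint: str = "fixture"

    @model_validator(mode="after")
    def _rank_limit_convention(self) -> "SourceDescriptor":
        expected = _RANK_LIMITS.get(self.source_id)
        if expected is not None and self.rank_limit != expected:
            raise ValueError(
                f"rank_limit for {self.source_id} must be {expected}"
            )
        return self


class MaskRule(BaseModel):
    """Databases hidden from sets of a given origin.

    ``masked`` pairs are (source_id, database); database ``None`` masks
    the whole source.
    """

    dataset_source: SetSource
    masked: list[tuple[str, Optional[str]]]


def default_mask_rules() -> list[MaskRule]:
    return [
        MaskRule(dataset_source=SetSource.GO, masked=[("gprofiler", None)]),
        MaskRule(
            dataset_source=SetSource.MSigDB,
            masked=[("enrichr", "MSigDB_Hallmark_2020")],
        ),
    ]


def _gene_key(genes: Sequence[str]) -> str:
    return "|".join(sorted(g.casefold() for g in genes))


class KnowledgeSource:
    """Base adapter: a descriptor plus a query method over gene lists."""

    def __init__(self, descriptor: SourceDescriptor):
        self.descriptor = descriptor
        self.transport_calls = 0

    @property
    def source_id(self) -> str:
        return self.descriptor.source_id

    def restricted(self, databases: list[str]) -> "KnowledgeSource":
        raise NotImplementedError

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        raise NotImplementedError


class FixtureEnrichmentSource(KnowledgeSource):
    """Offline enrichment service over a planted knowledge base.

    KB layout: ``{database: {gene-key: [[term, p_value, description?], ...]}}``
    where gene-key joins the case-folded sorted symbols with ``|``.
    Terms from all configured databases are pooled, ranked by p-value
    (ties by database order, then planted order) and truncated at the
    source rank limit.
    """

    def __init__(self, descriptor: SourceDescriptor, kb: dict):
        super().__init__(descriptor)
        self.kb = kb

    def restricted(self, databases: list[str]) -> "FixtureEnrichmentSource":
        desc = self.descriptor.model_copy(update={"databases": databases})
        src = FixtureEnrichmentSource(desc, self.kb)
        return src

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        if not genes:
            raise ValueError("enrichment query requires at least one gene")
        self.transport_calls += 1
        key = _gene_key(genes)
        pooled: list[tuple[float, int, int, str, Optional[str], str]] = []
        for di, db in enumerate(self.descriptor.databases):
            rows = self.kb.get(db, {}).get(key, [])
            for ri, row in enumerate(rows):
                term, p = row[0], float(row[1])
                desc = row[2] if len(row) > 2 else None
                pooled.append((p, di, ri, term, desc, db))
        pooled.sort(key=lambda t: (t[0], t[1], t[2]))
        pooled = pooled[: self.descriptor.rank_limit]
        used_dbs = []
        for _, _, _, _, _, db in pooled:
            if db not in used_dbs:
                used_dbs.append(db)
        return EvidenceItem(
            source_id=self.source_id,
            database_name=",".join(used_dbs),
            query_genes=list(genes),
            retrieved_terms=[
                RetrievedTerm(term=t, description=d, score=p)
                for p, _, _, t, d, _ in pooled
            ],
            retrieved_at_rank_limit=self.descriptor.rank_limit,
        )


class FixtureGeneCentricSource(KnowledgeSource):
    """Offline gene-centric service.

    KB layout: ``{database: {gene: [term, ...]}}`` (ranked lists) or, for
    summary-style databases, ``{database: {gene: "summary text"}}``.
    """

    def __init__(self, descriptor: SourceDescriptor, kb: dict):
        super().__init__(descriptor)
        self.kb = kb

    def restricted(self, databases: list[str]) -> "FixtureGeneCentricSource":
        desc = self.descriptor.model_copy(update={"databases": databases})
        return FixtureGeneCentricSource(desc, self.kb)

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        if len(genes) != 1:
            raise ValueError("gene-centric query takes a single gene symbol")
        self.transport_calls += 1
        gene = genes[0]
        pooled: list[tuple[int, int, str, str]] = []
        for di, db in enumerate(self.descriptor.databases):
            table = self.kb.get(db, {})
            entry = table.get(gene) or table.get(gene.casefold()) or table.get(
                gene.upper()
            )
            if entry is None:
                continue
            if isinstance(entry, str):
                pooled.append((di, 0, entry, db))
            else:
                for ri, term in enumerate(entry):
                    pooled.append((di, ri, term, db))
        pooled.sort(key=lambda t: (t[1], t[0]))
        pooled = pooled[: self.descriptor.rank_limit]
        used_dbs = []
        for di, _, _, db in pooled:
            if db not in used_dbs:
                used_dbs.append(db)
        return EvidenceItem(
            source_id=self.source_id,
            database_name=",".join(used_dbs),
            query_genes=list(genes),
            retrieved_terms=[RetrievedTerm(term=t) for _, _, t, _ in pooled],
            retrieved_at_rank_limit=self.descriptor.rank_limit,
        )


class SourceRegistry:
    """Active knowledge sources keyed by source id."""

    def __init__(self, sources: dict[str, KnowledgeSource] | None = None):
        self.sources: dict[str, KnowledgeSource] = dict(sources or {})

    def add(self, source: KnowledgeSource) -> None:
        self.sources[source.source_id] = source

    def enrichment_sources(self) -> list[KnowledgeSource]:
        return [
            s for sid, s in self.sources.items() if sid in ENRICHMENT_SOURCES
        ]

    def gene_centric_sources(self) -> list[KnowledgeSource]:
        return [
            s for sid, s in self.sources.items() if sid in GENE_CENTRIC_SOURCES
        ]

    def without(self, source_id: str) -> "SourceRegistry":
        return SourceRegistry(
            {sid: s for sid, s in self.sources.items() if sid != source_id}
        )


def apply_mask(
    registry: SourceRegistry,
    gene_set: GeneSet,
    rules: Sequence[MaskRule] | None = None,
) -> SourceRegistry:
    """Return a registry with the gene set's own curation source hidden."""
    rules = default_mask_rules() if rules is None else rules
    filtered = dict(registry.sources)
    for rule in rules:
        if rule.dataset_source is not gene_set.source:
            continue
        for source_id, database in rule.masked:
            if source_id not in filtered:
                continue
            if database is None:
                del filtered[source_id]
            else:
                src = filtered[source_id]
                kept = [d for d in src.descriptor.databases if d != database]
                filtered[source_id] = src.restricted(kept)
    return SourceRegistry(filtered)


class SignificantTermSet(BaseModel):
    """Enrichment terms passing the significance threshold, p ascending."""

    gene_set_id: str
    terms: list[tuple[str, float]]
    alpha: float

    @model_validator(mode="after")
    def _all_significant(self) -> "SignificantTermSet":
        bad = [t for t, p in self.terms if p > self.alpha]
        if bad:
            raise ValueError(f"terms above alpha={self.alpha}: {bad}")
        return self


def significant_terms(
    gene_set: GeneSet,
    source: KnowledgeSource,
    alpha: float = 0.05,
) -> SignificantTermSet:
    """Over-representation terms with p <= alpha, used as exact-match
    ground truth for the enrichment-term test."""
    item = source.query(gene_set.genes)
    kept = [
        (t.term, t.score)
        for t in item.retrieved_terms
        if t.score is not None and t.score <= alpha
    ]
    kept.sort(key=lambda tp: tp[1])
    return SignificantTermSet(gene_set_id=gene_set.set_id, terms=kept, alpha=alpha)


class CachedSource(KnowledgeSource):
    """Memoizes queries per run, keyed by (source, databases, genes).

    Gene order is canonicalized so permuted queries share one transport
    call; a ``disabled`` flag passes everything through.
    """

    def __init__(self, inner: KnowledgeSource, disabled: bool = False):
        super().__init__(inner.descriptor)
        self.inner = inner
        self.disabled = disabled
        self._cache: dict[tuple, EvidenceItem] = {}

    @property
    def transport_calls(self) -> int:  # type: ignore[override]
        return self.inner.transport_calls

    @transport_calls.setter
    def transport_calls(self, value: int) -> None:
        pass

    def restricted(self, databases: list[str]) -> "CachedSource":
        return CachedSource(self.inner.restricted(databases), self.disabled)

    def query(self, genes: Sequence[str]) -> EvidenceItem:
        if self.disabled:
            return self.inner.query(genes)
        key = (
            self.source_id,
            tuple(self.descriptor.databases),
            _gene_key(genes),
        )
        if key not in self._cache:
            self._cache[key] = self.inner.query(genes)
        return self._cache[key]


def default_descriptors() -> dict[str, SourceDescriptor]:
    return {
        "gprofiler": SourceDescriptor(
            source_id="gprofiler", databases=list(GPROFILER_DATABASES), rank_limit=5
        ),
        "enrichr": SourceDescriptor(
            source_id="enrichr", databases=list(ENRICHR_DATABASES), rank_limit=5
        ),
        "eutils": SourceDescriptor(
            source_id="eutils", databases=list(EUTILS_DATABASES), rank_limit=10
        ),
        "agentapi": SourceDescriptor(
            source_id="agentapi", databases=list(AGENTAPI_DATABASES), rank_limit=10
        ),
    }


def fixture_registry_from_kb(
    enrichment_kb: dict,
    gene_kb: dict,
    cache: bool = True,
) -> SourceRegistry:
    """Build the standard four-source registry over fixture KBs."""
    desc = default_descriptors()
    sources: list[KnowledgeSource] = [
        FixtureEnrichmentSource(desc["gprofiler"], enrichment_kb),
        FixtureEnrichmentSource(desc["enrichr"], enrichment_kb),
        FixtureGeneCentricSource(desc["eutils"], gene_kb),
        FixtureGeneCentricSource(desc["agentapi"], gene_kb),
    ]
    registry = SourceRegistry()
    for s in sources:
        registry.add(CachedSource(s) if cache else s)
    return registry


def load_fixture_registry(kb_dir: str | Path, cache: bool = True) -> SourceRegistry:
    kb_dir = Path(kb_dir)
    enrichment_kb = json.loads((kb_dir / "enrichment.json").read_text())
    gene_kb = json.loads((kb_dir / "genes.json").read_text())
    return fixture_registry_from_kb(enrichment_kb, gene_kb, cache=cache)
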