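"""The four-stage self-verification cascade.

generation -> verify(process-name claims) -> modification ->
verify(narrative claims) -> summarization.  The process name is thereby
verified twice: once directly and once again while the narrative's
gene-function claims are checked.  All text generation goes through a
pluggable backend run at temperature 0, so the pipeline is seed-free and
deterministic by construction whenever the backend and sources are.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

from .backends import LLMBackend, prompt_digest
from .prompts import LINKING_PHRASES, StagePromptSet
from .sources import (
    RetrievalError,
    SourceRegistry,
    apply_mask,
    MaskRule,
)
from .types import (
    CallRecord,
    Claim,
    ClaimOrigin,
    Decision,
    DecisionCategory,
    EvidenceItem,
    GeneSet,
    Narrative,
    PipelineResult,
    ProcessName,
    ReportEntry,
    Stage,
    VerificationReport,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed for a named gene set."""


@dataclass
class PipelineConfig:
    backend: LLMBackend
    registry: SourceRegistry
    prompts: StagePromptSet = field(default_factory=StagePromptSet)
    mask_rules: list[MaskRule] | None = None
    temperature: float = 0.0
    evidence_char_budget: int = 4000
    regenerate_narrative_always: bool = False


class _CallLogger:
    """Wraps the backend, recording request/response digests in order."""

    def __init__(self, backend: LLMBackend, temperature: float):
        self.backend = backend
        self.temperature = temperature
        self.records: list[CallRecord] = []

    def generate(self, prompt: str) -> str:
        response = self.backend.generate(prompt, self.temperature)
        self.records.append(
            CallRecord(
                backend_id=self.backend.identifier,
                request_digest=prompt_digest(prompt),
                response_digest=prompt_digest(response),
            )
        )
        return response


def _split_name_and_narrative(text: str) -> tuple[str, str]:
    """First non-empty line is the process name; the rest is narrative."""
    lines = text.strip().splitlines()
    if not lines:
        return "", ""
    name = lines[0].strip()
    narrative = "\n".join(lines[1:]).strip()
    return name, narrative


def run_generation(
    gene_set: GeneSet,
    backend: LLMBackend | _CallLogger,
    prompts: StagePromptSet | None = None,
    temperature: float = 0.0,
) -> tuple[ProcessName, Narrative]:
    """Stage g: propose an initial process name and narrative.

    The prompt lists the gene symbols comma-separated, each exactly once.
    """
    prompts = prompts or StagePromptSet()
    prompt = prompts.render("generation", genes=", ".join(gene_set.genes))
    if isinstance(backend, _CallLogger):
        text = backend.generate(prompt)
    else:
        text = backend.generate(prompt, temperature)
    name, narrative = _split_name_and_narrative(text)
    if not name:
        raise StageError(f"generation returned empty text for {gene_set.set_id!r}")
    return (
        ProcessName(text=name, stage=Stage.initial),
        Narrative(text=narrative, stage=Stage.initial),
    )


def make_claims_from_process(
    gene_set: GeneSet, p: ProcessName, prompts: StagePromptSet | None = None
) -> list[Claim]:
    """One hypothesis claim linking the full gene list to the name."""
    prompts = prompts or StagePromptSet()
    raw = prompts.render(
        "claim_from_process", genes=", ".join(gene_set.genes), process=p.text
    )
    return [
        Claim.create(
            genes=list(gene_set.genes),
            function_phrase=p.text,
            origin=ClaimOrigin.process_name,
            raw_text=raw,
        )
    ]


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[A-Za-z0-9_\-]+")


def extract_entities(
    raw_text: str, vocabulary: list[str]
) -> tuple[list[str], str]:
    """Pull gene symbols and the function phrase out of a claim sentence.

    Symbols are matched case-insensitively token-by-token against the
    input set's vocabulary; the function phrase is the text trailing the
    first linking statement.  No vocabulary hit leaves the gene list
    empty (the claim is later marked unverified).
    """
    vocab = {v.casefold(): v for v in vocabulary}
    genes: list[str] = []
    for token in _TOKEN.findall(raw_text):
        hit = vocab.get(token.casefold())
        if hit is not None and hit not in genes:
            genes.append(hit)
    phrase = ""
    lowered = raw_text.lower()
    for link in LINKING_PHRASES:
        idx = lowered.find(link)
        if idx >= 0:
            phrase = raw_text[idx + len(link):].strip().rstrip(".!?").strip()
            break
    if not genes:
        return [], ""
    return genes, phrase


def make_claims_from_narrative(
    gene_set: GeneSet, a: Narrative
) -> list[Claim]:
    """Mine one claim per gene-function pair from narrative sentences.

    Each sentence containing input-set symbols and a linking statement
    yields one claim per symbol against that sentence's function phrase.
    """
    claims: list[Claim] = []
    seen_raw: set[str] = set()
    prompts = StagePromptSet()
    for sentence in _SENTENCE_SPLIT.split(a.text):
        sentence = sentence.strip()
        if not sentence:
            continue
        genes, phrase = extract_entities(sentence, gene_set.genes)
        if not genes or not phrase:
            continue
        for gene in genes:
            raw = prompts.render("claim_from_narrative", gene=gene, function=phrase)
            if raw in seen_raw:
                continue
            seen_raw.add(raw)
            claims.append(
                Claim.create(
                    genes=[gene],
                    function_phrase=phrase,
                    origin=ClaimOrigin.narrative,
                    raw_text=raw,
                )
            )
    return claims


def parse_decision(judge_text: str) -> Decision:
    """Map the judge's free text to a decision category.

    First match wins, scanning case-insensitively for "partially
    supported", then "refuted", then "supported" (in that order, since
    "supported" is a substring of "partially supported"); no explicit
    decision word means unknown.
    """
    lowered = judge_text.lower()
    for needle, category in (
        ("partially supported", DecisionCategory.partially_supported),
        ("refuted", DecisionCategory.refuted),
        ("supported", DecisionCategory.supported),
    ):
        if needle in lowered:
            return Decision(category=category, rationale=judge_text.strip())
    return Decision(category=DecisionCategory.unknown, rationale=judge_text.strip())


def render_evidence_digest(
    evidence: list[EvidenceItem], char_budget: int = 4000
) -> str:
    """Plain-text evidence block for the judge, truncated at whole-term
    boundaries once the character budget is reached."""
    lines: list[str] = []
    total = 0
    for item in evidence:
        for t in item.retrieved_terms:
            line = f"- [{item.source_id}/{item.database_name}] {t.term}"
            if t.description:
                line += f" — {t.description}"
            if total + len(line) + 1 > char_budget:
                return "\n".join(lines)
            lines.append(line)
            total += len(line) + 1
    return "\n".join(lines) if lines else "(no evidence retrieved)"


def verify_claim(
    claim: Claim,
    registry: SourceRegistry,
    judge: LLMBackend | _CallLogger,
    prompts: StagePromptSet | None = None,
    temperature: float = 0.0,
    evidence_char_budget: int = 4000,
) -> tuple[list[EvidenceItem], Decision]:
    """Query arity-matching sources and ask the judge for a decision.

    Multi-gene claims go to the enrichment services; single-gene claims
    to the gene-centric ones.  Claims without extractable gene symbols
    are unverified and trigger no queries; if every source fails at
    transport level the decision is unknown with the failures recorded.
    """
    prompts = prompts or StagePromptSet()
    if not claim.genes:
        return [], Decision(
            category=DecisionCategory.unverified,
            rationale="no gene symbols available for querying knowledge sources",
        )
    if len(claim.genes) > 1:
        sources = registry.enrichment_sources()
    else:
        sources = registry.gene_centric_sources()
    evidence: list[EvidenceItem] = []
    failures: list[str] = []
    for source in sources:
        try:
            evidence.append(source.query(claim.genes))
        except RetrievalError as exc:
            failures.append(f"{source.source_id}: {exc}")
    if sources and not evidence and failures:
        return [], Decision(
            category=DecisionCategory.unknown,
            rationale="all sources failed: " + "; ".join(failures),
        )
    digest = render_evidence_digest(evidence, evidence_char_budget)
    prompt = prompts.render(
        "verification_judgment",
        claim=claim.raw_text,
        function=claim.function_phrase or "(none)",
        evidence=digest,
    )
    if isinstance(judge, _CallLogger):
        text = judge.generate(prompt)
    else:
        text = judge.generate(prompt, temperature)
    return evidence, parse_decision(text)


def verify_report(
    claims: list[Claim],
    target_stage: ClaimOrigin,
    registry: SourceRegistry,
    judge: LLMBackend | _CallLogger,
    prompts: StagePromptSet | None = None,
    temperature: float = 0.0,
    evidence_char_budget: int = 4000,
) -> VerificationReport:
    entries = []
    for claim in claims:
        evidence, decision = verify_claim(
            claim, registry, judge, prompts, temperature, evidence_char_budget
        )
        entries.append(ReportEntry(claim=claim, evidence=evidence, decision=decision))
    return VerificationReport(target_stage=target_stage, entries=entries)


def render_report(report: VerificationReport) -> str:
    """Human/judge-readable rendering used inside the modification prompt."""
    blocks = []
    for e in report.entries:
        lines = [f"Claim: {e.claim.raw_text}", f"Decision: {e.decision.category.value}"]
        for item in e.evidence:
            for t in item.retrieved_terms:
                lines.append(f"  * {t.term}")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) if blocks else "(empty report)"


def report_digest(report: VerificationReport) -> str:
    return hashlib.sha256(render_report(report).encode()).hexdigest()[:16]


def run_modification(
    gene_set: GeneSet,
    p_ini: ProcessName,
    a_ini: Narrative,
    report_p: VerificationReport,
    backend: LLMBackend | _CallLogger,
    prompts: StagePromptSet | None = None,
    temperature: float = 0.0,
    regenerate_narrative_always: bool = False,
) -> tuple[ProcessName, Narrative]:
    """Stage m: revise or retain the initial name given the report.

    An all-supported report retains the name outright (no backend call
    for the name); otherwise the backend's revision is adopted.  The
    narrative is regenerated when the name changed (or always, under the
    config flag); an empty backend response retains the initial values
    with a warning.
    """
    prompts = prompts or StagePromptSet()
    if report_p.target_stage is not ClaimOrigin.process_name:
        raise ValueError("run_modification requires a process-name report")
    if report_p.all_supported():
        return (
            ProcessName(text=p_ini.text, stage=Stage.modified),
            Narrative(text=a_ini.text, stage=Stage.modified),
        )
    prompt = prompts.render(
        "modification",
        genes=", ".join(gene_set.genes),
        process=p_ini.text,
        narrative=a_ini.text,
        report=render_report(report_p),
    )
    if isinstance(backend, _CallLogger):
        text = backend.generate(prompt)
    else:
        text = backend.generate(prompt, temperature)
    name, narrative = _split_name_and_narrative(text)
    if not name:
        logger.warning(
            "modification backend returned empty text for %s; retaining initial",
            gene_set.set_id,
        )
        return (
            ProcessName(text=p_ini.text, stage=Stage.modified),
            Narrative(text=a_ini.text, stage=Stage.modified),
        )
    changed = name.strip().casefold() != p_ini.text.strip().casefold()
    if narrative and (changed or regenerate_narrative_always):
        new_narrative = narrative
    else:
        new_narrative = a_ini.text
    return (
        ProcessName(text=name, stage=Stage.modified),
        Narrative(text=new_narrative, stage=Stage.modified),
    )


def run_summarization(
    gene_set: GeneSet,
    p_mod: ProcessName,
    a_mod: Narrative,
    report_a: VerificationReport,
    backend: LLMBackend | _CallLogger,
    prompts: StagePromptSet | None = None,
    temperature: float = 0.0,
) -> tuple[ProcessName, Narrative]:
    """Stage s: consolidate everything into the final outputs."""
    prompts = prompts or StagePromptSet()
    if report_a.target_stage is not ClaimOrigin.narrative:
        raise ValueError("run_summarization requires a narrative report")
    prompt = prompts.render(
        "summarization",
        genes=", ".join(gene_set.genes),
        process=p_mod.text,
        narrative=a_mod.text,
        report_digest=report_digest(report_a),
    )
    if isinstance(backend, _CallLogger):
        text = backend.generate(prompt)
    else:
        text = backend.generate(prompt, temperature)
    name, narrative = _split_name_and_narrative(text)
    if not name:
        raise StageError(
            f"summarization returned empty text for {gene_set.set_id!r}"
        )
    return (
        ProcessName(text=name, stage=Stage.final),
        Narrative(text=narrative or a_mod.text, stage=Stage.final),
    )


def run_pipeline(gene_set: GeneSet, config: PipelineConfig) -> PipelineResult:
    """Execute the full cascade on one gene set.

    Stage order is fixed: generation, process-name claims, verification,
    modification, narrative claims, verification, summarization.  Both
    verification reports are attached and every backend call is logged.
    """
    call = _CallLogger(config.backend, config.temperature)
    registry = apply_mask(config.registry, gene_set, config.mask_rules)
    prompts = config.prompts
    budget = config.evidence_char_budget

    p_ini, a_ini = run_generation(gene_set, call, prompts)
    claims_p = make_claims_from_process(gene_set, p_ini, prompts)
    report_p = verify_report(
        claims_p, ClaimOrigin.process_name, registry, call, prompts,
        evidence_char_budget=budget,
    )
    p_mod, a_mod = run_modification(
        gene_set, p_ini, a_ini, report_p, call, prompts,
        regenerate_narrative_always=config.regenerate_narrative_always,
    )
    claims_a = make_claims_from_narrative(gene_set, a_mod)
    report_a = verify_report(
        claims_a, ClaimOrigin.narrative, registry, call, prompts,
        evidence_char_budget=budget,
    )
    p_final, a_final = run_summarization(
        gene_set, p_mod, a_mod, report_a, call, prompts
    )
    return PipelineResult(
        gene_set_id=gene_set.set_id,
        p_initial=p_ini,
        a_initial=a_ini,
        report_p=report_p,
        p_modified=p_mod,
        a_modified=a_mod,
        report_a=report_a,
        p_final=p_final,
        a_final=a_final,
        call_log=call.records,
    )
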