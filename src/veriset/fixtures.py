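"""Deterministic offline stand-ins for every external dependency.

A :class:`FixtureWorld` bundles a toy ontology, planted gene-function
annotations, and a scripted LLM transcript such that the full pipeline
runs with no network access and recovers each set's planted process name
through the verification evidence: the scripted generation stage emits a
perturbed name, the enrichment fixtures rank the planted truth first, and
the modification stage is steered back to it.  Negative-control sets have
their evidence withheld, so their perturbed names survive to the final
output — recovery must fail for them.

Everything is fully determined by the seed and size parameters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import ontology as onto
from .backends import RecordingBackend, ScriptedBackend
from .pipeline import PipelineConfig, run_pipeline
from .sources import SourceRegistry, fixture_registry_from_kb
from .types import GeneSet, PipelineResult

_WORDS = [
    "protein", "lipid", "ion", "membrane", "signal", "transport", "binding",
    "regulation", "assembly", "response", "biosynthesis", "catabolism",
    "oxidation", "repair", "division", "adhesion", "migration", "translation",
    "folding", "secretion",
]
_RELATIONS = [
    "is_a", "part_of", "regulates", "negatively_regulates", "positively_regulates",
]


class FixtureError(ValueError):
    """Requested world sizes are infeasible."""


def _hash_bucket(token: str, dim: int) -> int:
    import hashlib

    return int(hashlib.md5(token.encode()).hexdigest(), 16) % dim


class ToyEncoder:
    """Deterministic sparse count vector over a hashed vocabulary.

    Tokens are case-folded, punctuation-stripped and hashed into a fixed
    number of buckets; identical text always embeds identically, so every
    downstream metric is bit-reproducible.
    """

    def __init__(self, dim: int = 4096):
        self.identifier = f"toy-hash-{dim}"
        self.dim = dim

    def embed(self, text: str) -> np.ndarray:
        from .metrics import tokenize

        vec = np.zeros(self.dim)
        for token in tokenize(text):
            vec[_hash_bucket(token, self.dim)] += 1.0
        return vec


_DEFAULT_ENCODER = ToyEncoder()


def toy_encoder(text: str) -> np.ndarray:
    return _DEFAULT_ENCODER.embed(text)


@dataclass
class FixtureWorld:
    seed: int
    ontology: onto.OntologyGraph
    obo_text: str
    gene_sets: list[GeneSet]
    negative_ids: set[str]
    planted_truth: dict[str, str]
    enrichment_kb: dict
    gene_kb: dict
    transcript: dict[str, str]
    background: list[str] = field(default_factory=list)

    def make_registry(self, cache: bool = True) -> SourceRegistry:
        return fixture_registry_from_kb(
            self.enrichment_kb, self.gene_kb, cache=cache
        )

    def make_backend(self) -> ScriptedBackend:
        return ScriptedBackend(self.transcript, identifier="scripted:world")

    def make_steering_backend(self) -> "_SteeringBackend":
        """Evidence-steered responder that handles *any* prompt, for runs
        whose masking/registry deviates from the recorded transcript."""
        truth_by_genes = {
            frozenset(g.casefold() for g in gs.genes): self.planted_truth[gs.set_id]
            for gs in self.gene_sets
        }
        return _SteeringBackend(truth_by_genes)

    def make_config(self) -> PipelineConfig:
        return PipelineConfig(backend=self.make_backend(), registry=self.make_registry())

    def run_all(self) -> dict[str, PipelineResult]:
        """Replay the full pipeline on every set from the transcript."""
        return {
            gs.set_id: run_pipeline(gs, self.make_config()) for gs in self.gene_sets
        }


class _SteeringBackend:
    """Deterministic evidence-driven responder used to build transcripts.

    It answers each stage prompt using only what the prompt contains:
    generation perturbs the planted name, judgment compares the claimed
    function against the listed evidence terms, modification adopts the
    top evidence term (or keeps the current name when there is none), and
    summarization passes the current name through.
    """

    identifier = "steering"

    def __init__(self, world_truth_by_genes: dict[frozenset, str]):
        self._truth = world_truth_by_genes

    @staticmethod
    def _line(prompt: str, prefix: str) -> str:
        for line in prompt.splitlines():
            if line.startswith(prefix):
                return line[len(prefix):].strip()
        return ""

    @staticmethod
    def _block(prompt: str, start: str, end: str | None) -> str:
        text = prompt.split(start, 1)
        if len(text) < 2:
            return ""
        rest = text[1]
        if end is not None and end in rest:
            rest = rest.split(end, 1)[0]
        return rest.strip()

    def generate(self, prompt: str, temperature: float = 0.0) -> str:
        from .metrics import normalize

        if prompt.startswith("[stage:generation]"):
            genes = [
                g.strip()
                for g in self._line(prompt, "Genes:").split(",")
                if g.strip()
            ]
            truth = self._truth.get(frozenset(g.casefold() for g in genes))
            name = f"putative {truth}" if truth else "uncharacterized process"
            narrative = " ".join(f"{g} is involved in {name}." for g in genes)
            return f"{name}\n\n{narrative}"

        if prompt.startswith("[stage:verification_judgment]"):
            function = self._line(prompt, "Function:")
            evidence = self._block(prompt, "Evidence:\n", None)
            terms = re.findall(r"^- \[[^\]]+\] ([^—\n]+?)(?: — .*)?$",
                               evidence, flags=re.M)
            terms = [t.strip() for t in terms]
            if not terms:
                return "No database information was returned for this claim."
            if any(normalize(t) == normalize(function) for t in terms):
                return f"Supported: the databases list '{terms[0]}' for these genes."
            return "Refuted: the databases list different functions for these genes."

        if prompt.startswith("[stage:modification]"):
            current = self._line(prompt, "Current name:")
            genes = [
                g.strip()
                for g in self._line(prompt, "Genes:").split(",")
                if g.strip()
            ]
            report = self._block(prompt, "Verification report:\n", None)
            terms = [
                line.strip()[2:].strip()
                for line in report.splitlines()
                if line.strip().startswith("* ")
            ]
            if terms:
                name = terms[0]
                narrative = " ".join(f"{g} is involved in {name}." for g in genes)
                return f"{name}\n\n{narrative}"
            narrative = self._block(prompt, "Narrative:\n", "Verification report:")
            return f"{current}\n\n{narrative}"

        if prompt.startswith("[stage:summarization]"):
            current = self._line(prompt, "Current name:")
            narrative = self._block(prompt, "Narrative:\n", "Report digest:")
            return f"{current}\n\n{narrative}"

        raise ValueError("steering backend received an unrecognized prompt")


def _make_term_names(rng: np.random.Generator, n_terms: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n_terms:
        k = int(rng.integers(2, 4))
        words = rng.choice(_WORDS, size=k, replace=False)
        name = " ".join(words)
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _build_ontology(
    rng: np.random.Generator, names: list[str]
) -> tuple[onto.OntologyGraph, str]:
    graph = nx.MultiDiGraph()
    ids = [f"T:{i + 1:07d}" for i in range(len(names))]
    for tid, name in zip(ids, names):
        graph.add_node(tid, name=name)
    edges: list[tuple[str, str, str]] = []
    for i in range(1, len(ids)):
        n_parents = int(rng.integers(1, 3)) if i > 1 else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = _RELATIONS[int(rng.integers(0, len(_RELATIONS)))]
            graph.add_edge(ids[i], ids[int(p)], key=rel)
            edges.append((ids[i], ids[int(p)], rel))
    lines = ["format-version: 1.2", ""]
    for i, (tid, name) in enumerate(zip(ids, names)):
        lines += ["[Term]", f"id: {tid}", f"name: {name}"]
        for child, parent, rel in edges:
            if child != tid:
                continue
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    return onto.from_networkx(graph), "\n".join(lines)


def generate_world(
    seed: int,
    n_terms: int = 50,
    n_genes: int = 200,
    n_sets: int = 10,
    n_negative: int = 2,
) -> FixtureWorld:
    """Build a complete deterministic offline world.

    Each positive set's planted process name is the rank-1 enrichment hit
    in the fixture knowledge bases (p-values assigned by rank as
    rank/1000) and every member gene carries the planted name among its
    gene-centric annotations; the final ``n_negative`` sets get no
    annotations at all and serve as negative controls.  The scripted
    transcript is recorded by dry-running the pipeline with an
    evidence-steered deterministic responder.
    """
    if min(n_terms, n_genes, n_sets) < 1 or n_negative < 0:
        raise FixtureError("all sizes must be >= 1 (n_negative >= 0)")
    if n_negative >= n_sets:
        raise FixtureError("need at least one positive set")
    if n_terms < n_sets + 4:
        raise FixtureError("need n_terms >= n_sets + 4 for distinct distractors")
    rng = np.random.default_rng(seed)
    names = _make_term_names(rng, n_terms)
    ontology, obo_text = _build_ontology(rng, names)

    genes = [f"GX{i + 1:04d}" for i in range(n_genes)]
    sizes = [int(rng.integers(4, 9)) for _ in range(n_sets)]
    if sum(sizes) > n_genes:
        raise FixtureError(
            f"gene pool of {n_genes} too small for {n_sets} sets "
            f"({sum(sizes)} genes needed)"
        )
    pool = list(rng.permutation(genes))
    truth_terms = [names[int(i)] for i in rng.choice(n_terms, n_sets, replace=False)]

    gene_sets: list[GeneSet] = []
    planted: dict[str, str] = {}
    negative_ids: set[str] = set()
    enrichment_kb: dict = {"GO": {}, "KEGG_2021_Human": {}}
    gene_kb: dict = {"ppi": {}, "gene": {}}
    cursor = 0
    for i in range(n_sets):
        set_genes = pool[cursor : cursor + sizes[i]]
        cursor += sizes[i]
        set_id = f"SET{i + 1:03d}"
        truth = truth_terms[i]
        gene_sets.append(
            GeneSet(set_id=set_id, genes=set_genes, ground_truth=truth)
        )
        planted[set_id] = truth
        if i >= n_sets - n_negative:
            negative_ids.add(set_id)
            continue
        distractors = [t for t in names if t != truth]
        picks = [distractors[int(j)] for j in rng.choice(len(distractors), 3, False)]
        ranked = [[truth, 0.001]] + [
            [t, (r + 2) / 1000] for r, t in enumerate(picks)
        ]
        key = "|".join(sorted(g.casefold() for g in set_genes))
        enrichment_kb["GO"][key] = ranked
        enrichment_kb["KEGG_2021_Human"][key] = ranked
        for g in set_genes:
            gene_kb["ppi"][g] = [truth] + picks[:2]
            gene_kb["gene"][g] = f"{g} is annotated to {truth}."

    truth_by_genes = {
        frozenset(g.casefold() for g in gs.genes): planted[gs.set_id]
        for gs in gene_sets
    }
    steering = _SteeringBackend(truth_by_genes)
    recorder = RecordingBackend(steering)
    registry = fixture_registry_from_kb(enrichment_kb, gene_kb)
    config = PipelineConfig(backend=recorder, registry=registry)
    for gs in gene_sets:
        run_pipeline(gs, config)

    return FixtureWorld(
        seed=seed,
        ontology=ontology,
        obo_text=obo_text,
        gene_sets=gene_sets,
        negative_ids=negative_ids,
        planted_truth=planted,
        enrichment_kb=enrichment_kb,
        gene_kb=gene_kb,
        transcript=dict(sorted(recorder.transcript.items())),
        background=list(names),
    )


def write_world(world: FixtureWorld, outdir: str | Path) -> None:
    """Write the world as plain-text files: ontology.obo, sets.gmt,
    kb/*.json, transcript.json, background.txt."""
    outdir = Path(outdir)
    (outdir / "kb").mkdir(parents=True, exist_ok=True)
    (outdir / "ontology.obo").write_text(world.obo_text + "\n")
    gmt_lines = [
        "\t".join([gs.set_id, gs.ground_truth or "", *gs.genes])
        for gs in world.gene_sets
    ]
    (outdir / "sets.gmt").write_text("\n".join(gmt_lines) + "\n")
    (outdir / "kb" / "enrichment.json").write_text(
        json.dumps(world.enrichment_kb, indent=1, sort_keys=True)
    )
    (outdir / "kb" / "genes.json").write_text(
        json.dumps(world.gene_kb, indent=1, sort_keys=True)
    )
    (outdir / "transcript.json").write_text(
        json.dumps(world.transcript, indent=1, sort_keys=True)
    )
    (outdir / "background.txt").write_text("\n".join(world.background) + "\n")
    meta = {
        "seed": world.seed,
        "negative_ids": sorted(world.negative_ids),
        "planted_truth": world.planted_truth,
    }
    (outdir / "world.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
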