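"""Evaluation metrics for generated process names.

Covers recall-oriented ROUGE (1, 2, L) between a generated name and its
curated ground truth, embedding cosine similarity, the background
percentile of that similarity among a fixed candidate-term list, the
hierarchical comparison against ontology ancestors within a hop bound,
exact-match accuracy for enrichment-term testing, Wilson score intervals
for agreement proportions, and batch-sampled mean/s.d. aggregation.

One tokenizer — lower-case, punctuation stripped, whitespace split — is
shared by ROUGE and exact matching so the metrics stay comparable.
"""

from __future__ import annotations

import string as _string
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .ontology import OntologyGraph, ancestors_within_hops

_PUNCT_TABLE = str.maketrans({c: " " for c in _string.punctuation})


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    if lowercase:
        text = text.lower()
    return text.translate(_PUNCT_TABLE).split()


def normalize(text: str) -> str:
    return " ".join(tokenize(text))


class EncoderContract(Protocol):
    """Anything that deterministically embeds text into a fixed-length
    vector (a biomedical sentence encoder live, a toy bag-of-words
    encoder offline)."""

    identifier: str

    def embed(self, text: str) -> np.ndarray: ...


@dataclass
class RougeConfig:
    beta: float = 1.0
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class RougeScore:
    rouge1: Optional[float]
    rouge2: Optional[float]
    rougeL: Optional[float]


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def rouge_n(
    hyp: str, ref: str, n: int, config: RougeConfig | None = None
) -> Optional[float]:
    """Recall of reference n-grams, with clipped match counts.

    Returns None (missing, not 0) when the reference is shorter than
    ``n`` tokens, where the score is undefined.
    """
    config = config or RougeConfig()
    ref_tokens = tokenize(ref, config.lowercase)
    hyp_tokens = tokenize(hyp, config.lowercase)
    ref_grams = _ngrams(ref_tokens, n)
    if not ref_grams:
        return None
    hyp_grams = _ngrams(hyp_tokens, n)
    matched = sum((ref_grams & hyp_grams).values())
    return matched / sum(ref_grams.values())


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, 1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[-1]))
        prev = curr
    return prev[-1]


def rouge_l(hyp: str, ref: str, config: RougeConfig | None = None) -> Optional[float]:
    """LCS-based F-measure: F_beta of R = LCS/m and P = LCS/n, where m
    and n are the reference and hypothesis token lengths."""
    config = config or RougeConfig()
    ref_tokens = tokenize(ref, config.lowercase)
    hyp_tokens = tokenize(hyp, config.lowercase)
    if not ref_tokens or not hyp_tokens:
        return None
    lcs = _lcs_length(ref_tokens, hyp_tokens)
    if lcs == 0:
        return 0.0
    r = lcs / len(ref_tokens)
    p = lcs / len(hyp_tokens)
    b2 = config.beta**2
    return (1 + b2) * r * p / (r + b2 * p)


def rouge_all(hyp: str, ref: str, config: RougeConfig | None = None) -> RougeScore:
    return RougeScore(
        rouge1=rouge_n(hyp, ref, 1, config),
        rouge2=rouge_n(hyp, ref, 2, config),
        rougeL=rouge_l(hyp, ref, config),
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def semantic_similarity(p: str, g: str, encoder: EncoderContract) -> float:
    """Cosine similarity of the two texts' embeddings, in [-1, 1]."""
    return cosine_similarity(encoder.embed(p), encoder.embed(g))


@dataclass
class BackgroundSet:
    """Ordered candidate terms; order fixed at construction breaks ties."""

    terms: list[str]

    def __len__(self) -> int:
        return len(self.terms)


def assemble_background(
    go_terms: Sequence[str],
    nest_terms: Sequence[str],
    msigdb_terms: Sequence[str],
) -> BackgroundSet:
    """Concatenate the three candidate lists in order, no deduplication,
    so the sizes add exactly."""
    return BackgroundSet(terms=list(go_terms) + list(nest_terms) + list(msigdb_terms))


@dataclass
class PercentileResult:
    percentile: float
    sim_ground_truth: float
    tied: bool
    ground_truth_appended: bool = False


def background_percentile(
    p: str,
    ground_truth: str,
    q: BackgroundSet,
    encoder: EncoderContract,
) -> PercentileResult:
    """Where sim(p, ground truth) ranks among sim(p, candidate) for all
    candidates.

    percentile = 100 x #{candidates with similarity strictly below
    sim(p, ground truth)} / |Q|.  Ties with other candidates are
    reported via a flag; a ground truth absent from Q is appended and
    flagged.
    """
    if len(q) == 0:
        raise ValueError("background set is empty")
    terms = list(q.terms)
    appended = False
    if ground_truth not in terms:
        terms = terms + [ground_truth]
        appended = True
    p_vec = encoder.embed(p)
    sims = np.array([cosine_similarity(p_vec, encoder.embed(t)) for t in terms])
    sim_gt = semantic_similarity(p, ground_truth, encoder)
    below = int(np.sum(sims < sim_gt))
    equal_others = int(np.sum(sims == sim_gt)) - terms.count(ground_truth)
    return PercentileResult(
        percentile=100.0 * below / len(terms),
        sim_ground_truth=sim_gt,
        tied=equal_others > 0,
        ground_truth_appended=appended,
    )


@dataclass
class HierarchicalComparison:
    sim_ground_truth: Optional[float]
    best_ancestor: Optional[str]
    sim_best_ancestor: Optional[float]
    ancestor_higher: bool
    skipped: bool = False


def hierarchical_comparison(
    p: str,
    ground_truth: str,
    graph: OntologyGraph,
    encoder: EncoderContract,
    k: int = 3,
) -> HierarchicalComparison:
    """Is the generated name more similar to an ancestor of the ground
    truth (within ``k`` hops) than to the ground truth itself?

    Ground truths are resolved to ontology ids by exact case-insensitive
    name match; unresolvable ones are flagged skipped.
    """
    term_id = ground_truth if ground_truth in graph else graph.resolve_name(ground_truth)
    if term_id is None:
        return HierarchicalComparison(
            sim_ground_truth=None,
            best_ancestor=None,
            sim_best_ancestor=None,
            ancestor_higher=False,
            skipped=True,
        )
    sim_gt = semantic_similarity(p, graph.name_of(term_id), encoder)
    best_name: Optional[str] = None
    best_sim: Optional[float] = None
    for anc_id in sorted(ancestors_within_hops(graph, term_id, k)):
        sim = semantic_similarity(p, graph.name_of(anc_id), encoder)
        if best_sim is None or sim > best_sim:
            best_sim = sim
            best_name = graph.name_of(anc_id)
    return HierarchicalComparison(
        sim_ground_truth=sim_gt,
        best_ancestor=best_name,
        sim_best_ancestor=best_sim,
        ancestor_higher=best_sim is not None and best_sim > sim_gt,
    )


@dataclass
class MatchResult:
    matched: int
    total: int
    accuracy: Optional[float]


def exact_match_accuracy(
    tested_terms: Sequence[str],
    significant_terms: Sequence[str],
    mode: str = "multiset",
) -> MatchResult:
    """Fraction of tested terms exactly matching a significant term.

    A tested term is accurate only when all its words match one ground-
    truth term: by default word-multiset equality after normalization
    (case-folded, punctuation stripped), making the criterion invariant
    to word order; ``mode="string"`` compares normalized strings instead.
    Zero tested terms leaves the accuracy undefined (None, not 0).
    """
    if mode not in ("multiset", "string"):
        raise ValueError(f"unknown match mode {mode!r}")
    if mode == "multiset":
        truth = [Counter(tokenize(t)) for t in significant_terms]
        matched = sum(
            1 for t in tested_terms if Counter(tokenize(t)) in truth
        )
    else:
        truth_s = {normalize(t) for t in significant_terms}
        matched = sum(1 for t in tested_terms if normalize(t) in truth_s)
    total = len(tested_terms)
    return MatchResult(
        matched=matched,
        total=total,
        accuracy=(matched / total) if total else None,
    )


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials > 0")
    lower, upper = proportion_confint(
        successes, trials, alpha=1 - confidence, method="wilson"
    )
    return float(lower), float(upper)


@dataclass
class BatchAggregate:
    mean: float
    sd: float
    batch_size: int
    n_batches: int


def batch_aggregate(
    scores: Sequence[float],
    batch_size: int,
    n_batches: int = 9,
    seed: int = 0,
) -> BatchAggregate:
    """Mean of batch means and the s.d. across batch means.

    Batches are drawn without replacement within each batch by a seeded
    RNG.  When ``batch_size * n_batches`` equals the sample size the
    batches form a shuffled partition, so the mean of batch means equals
    the plain mean exactly.
    """
    scores = np.asarray(list(scores), dtype=float)
    if batch_size > len(scores):
        raise ValueError("batch_size exceeds the number of scores")
    if batch_size < 1 or n_batches < 1:
        raise ValueError("batch_size and n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    if batch_size * n_batches == len(scores):
        perm = rng.permutation(len(scores))
        batches = perm.reshape(n_batches, batch_size)
    else:
        batches = np.stack(
            [
                rng.choice(len(scores), size=batch_size, replace=False)
                for _ in range(n_batches)
            ]
        )
    means = scores[batches].mean(axis=1)
    return BatchAggregate(
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)) if n_batches > 1 else 0.0,
        batch_size=batch_size,
        n_batches=n_batches,
    )
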