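# Methods

## The verification model

The pipeline treats functional annotation as hypothesis generation
followed by fact checking. Every affirmative statement in the model's
output is reduced to a *claim* — gene symbols plus a function phrase,
joined by a linking statement such as "is involved in" — and each claim
is scored against curated knowledge retrieved live (or from fixtures)
for exactly those genes. The operating assumptions are:

- a claim is *decidable from retrieval*: the union of the configured
  sources is treated as the ground truth for the claimed function;
- the judge is *extractive*: its decision must be one of the decision
  words, parsed with the precedence "partially supported" → "refuted" →
  "supported" (the first is checked before the last because "supported"
  is a substring of it); text with no decision word is *unknown*;
- symbol matching is case-insensitive while stored spellings are
  preserved, so human (upper-case) and mouse (title-case) symbols flow
  through one code path;
- at temperature 0 every backend contract is deterministic, so the
  pipeline needs no random seed anywhere.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `temperature` | 0 | backend sampling temperature; 0 gives reproducible runs |
| enrichment rank limit | 5 | terms kept per enrichment source (pooled over its databases, ranked by p-value) |
| gene-centric rank limit | 10 | records kept per gene-centric source |
| `evidence_char_budget` | 4000 chars | evidence digest passed to the judge, truncated at whole-term boundaries |
| `alpha` | 0.05 | significance threshold for enrichment-term ground truth |
| ancestor hop bound `k` | 3 | BFS depth for hierarchical comparison |
| ROUGE `β` | 1 | recall/precision balance in the LCS F-measure |
| batch sizes | 200 / 20 | batch-sampled aggregation defaults (large / small datasets), 9 batches |

Dispatch policy: a claim with two or more genes queries the enrichment
sources; a single-gene claim queries the gene-centric sources. The
narrative is regenerated during modification only when the process name
actually changed (configurable to always regenerate).

## Masking

Masking removes a source that trivially contains a dataset's own ground
truth: GO-tagged sets drop the g:Profiler-style source entirely;
MSigDB-tagged sets drop the MSigDB_Hallmark_2020 database from the
Enrichr-style source (keeping its other three pathway databases);
NeST-tagged and custom sets are unmasked. Masking is applied to the
registry before any query, so a masked (source, database) pair can
never appear in an evidence item — an invariant the suite asserts over
whole pipeline traces under randomized source tags.

## The fixture world

`generate_world(seed, n_terms, n_genes, n_sets, n_negative)` builds a
fully deterministic offline study system: a typed ontology DAG over the
five relations with 2–3-word term names; gene sets of 4–8 symbols drawn
disjointly from the pool; and knowledge bases in which each positive
set's planted name is the rank-1 hit (fixture p-values are assigned by
rank, p = rank/1000, so significance filtering is predictable) and each
member gene carries the planted name among its gene-centric
annotations. The scripted LLM transcript is recorded by dry-running the
pipeline with an evidence-steered responder that only uses what its
prompt contains: generation perturbs the planted name ("putative …"),
judgment string-matches the claimed function against the evidence
terms, modification adopts the top evidence term, summarization passes
the current name through.

What the world emulates: the logical structure of self-verification —
evidence either corrects a perturbed hypothesis or, when withheld
(negative controls), leaves it uncorrectable. What it does not emulate:
real gene symbols or GO vocabulary, linguistic variability of model
output, partial or conflicting evidence, retrieval noise, or encoder
semantics beyond token overlap. Passing the recovery test therefore
demonstrates that the pipeline's plumbing — claim extraction, masking,
evidence routing, decision parsing, revision logic — is correct, not
that any particular language model is accurate on real data. The
published aggregate scores of live systems depend on proprietary model
and encoder weights and live database states, and are out of scope as
numeric targets.

## Numerical and design choices

- **Tokenizer** (shared by ROUGE and exact matching): lower-case, strip
  punctuation to spaces, split on whitespace. Case-insensitive by
  default since term casing is typographical in this domain.
- **ROUGE-N** is recall over reference n-grams with clipped match
  counts; a reference shorter than `n` tokens yields a *missing* score
  (`None`), never 0. ROUGE-L uses a dynamic-programming LCS.
- **Background percentile** uses strictly-greater counting:
  `100 · #{sim < sim(P,G)} / |Q|`, with ties flagged and the candidate
  order fixed at construction; a ground truth absent from `Q` is
  appended and flagged. The background list is a plain concatenation —
  no deduplication — so source sizes add exactly.
- **Exact match** compares word multisets (order-invariant) by default;
  a strict normalized-string mode is available.
- **Hop counting** traverses all five relation types uniformly, one
  edge of any type per hop, mixed types allowed along a path; distances
  are minimal. Ground-truth names resolve to ontology ids by exact
  case-insensitive name match; unresolved names are flagged skipped.
- **Wilson intervals** come from `statsmodels` (`proportion_confint`,
  method "wilson"); the test suite checks them against the closed form
  evaluated independently.
- **Batch aggregation** draws `n_batches` seeded batches without
  replacement within each batch; when `batch_size · n_batches` equals
  the sample size the batches form a shuffled partition, making the
  mean of batch means equal the plain mean exactly. The s.d. is the
  sample s.d. (ddof 1) across batch means.
- **Caching** keys on (source, databases, case-folded sorted genes), so
  permuted gene lists share one transport call.
- **Degenerate inputs**: empty gene lists are rejected at parse with
  the set id named; claims without extractable symbols are *unverified*
  and trigger no queries; total transport failure for a claim degrades
  to *unknown* rather than aborting; an empty modification response
  retains the initial outputs with a warning.

## Problem sizes

The shared test world uses 30 terms, 120 genes, 10 sets (2 negative);
the acceptance run uses 40 terms, 160 genes, 12 sets (3 negative).
These sizes exercise every code path — multi-gene and single-gene
claims, masking, negative controls — while keeping the whole offline
suite in the seconds range; recovery results are invariant across
seeds because the construction guarantees rank-1 retrieval of each
planted name.

## Known limitations

- The claim grammar is one deliberate reading: one claim links the full
  gene list to the process name, and narrative claims are mined per
  gene–function pair from sentences containing a linking statement.
  Other segmentations are plausible; the grammar lives in the prompt
  templates and is overridable.
- Live HTTP adapters are thin and untested against the real services;
  the package's guarantees are about the contract, which the fixture
  implementations satisfy exactly.
- The toy encoder measures token overlap, not meaning: synonymous terms
  with disjoint tokens score 0. Plug a biomedical sentence encoder into
  the `EncoderContract` for semantic evaluation.
- No gene-identifier aliasing: symbols are taken as given.
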