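# veriset — self-verifying gene-set annotation

Gene-set analysis asks what biological process a group of co-behaving
genes `D = {g_1, …, g_N}` carries out. Large language models can propose
a process name `P` and an analytical narrative `A` for such a set, but
they also hallucinate: plausible function statements with no backing in
the curated literature. `veriset` implements an agent pipeline that
mitigates this by **verifying its own output against expert-curated
knowledge sources** before committing to an answer, plus the full
evaluation suite used to judge such systems.

It is written for computational biologists who want (a) a fact-checked
functional annotation workflow whose every external dependency — the
language model, the text encoder, the enrichment and gene databases —
is a pluggable contract with a deterministic offline substitute, and
(b) reference implementations of the associated metrics.

## The pipeline

Four stages, run at temperature 0 so the whole cascade is deterministic:

1. **Generation** `(P_ini, A_ini) = g(D)` — a backend proposes an
   initial name and narrative for the comma-separated gene list.
2. **Self-verification of `P_ini`** — the hypothesis claim
   "`g_1, …, g_N` is involved in `P_ini`" is checked: the gene symbols
   are sent to arity-matching knowledge sources (multi-gene claims to
   enrichment services, rank limit 5; single-gene claims to gene-centric
   services, rank limit 10), and a judge backend turns the retrieved
   evidence into a decision — *supported*, *partially supported*,
   *refuted*, *unknown* (no explicit decision), or *unverified* (no gene
   symbols to query). The result is a verification report `R_P`.
3. **Modification** `(P_mod, A_mod) = m(P_ini, A_ini, R_P)` — an
   all-supported report retains the name; otherwise the backend revises
   it in light of the evidence.
4. **Second verification + summarization** — one claim per
   gene–function pair is mined from `A_mod`, verified the same way
   (report `R_A`), and `(P, A) = s(P_mod, A_mod, R_A)` produces the
   final output. The process name is thereby verified twice.

A masking strategy prevents leakage during verification: sets curated
from GO never see the g:Profiler-style service (which contains GO), and
MSigDB-derived sets never see the MSigDB_Hallmark_2020 database inside
the Enrichr-style service.

## Evaluation metrics

Against a curated ground-truth name `G`, the package computes:

- **ROUGE-1/2/L** (recall-oriented):
  `ROUGE-N = Σ count_match(g_N) / Σ count(g_N)` over reference n-grams,
  and `ROUGE-L = (1+β²)·R·P / (R + β²·P)` with `R = LCS/m`, `P = LCS/n`
  (β = 1 by default);
- **semantic similarity** `cos(P⃗, G⃗)` under any encoder contract (a
  deterministic hashed bag-of-words encoder ships for offline use);
- **background percentile**: where `sim(P, G)` ranks among `sim(P, Q_i)`
  for a fixed candidate-term list `Q` (strictly-greater counting, ties
  flagged);
- **hierarchical comparison**: whether `P` is more similar to an
  ancestor of `G` — within 3 hops over the five ontology relations
  is_a / part_of / regulates / negatively_regulates /
  positively_regulates — than to `G` itself;
- **exact-match enrichment testing** against terms with `p ≤ 0.05`
  (word-multiset equality after normalization);
- **Wilson score intervals** for agreement proportions and
  **batch-sampled mean ± s.d.** aggregation.

## Worked example (fully offline)

```bash
veriset fixtures generate --seed 1 --terms 20 --genes 60 --sets 4 --negatives 1 --out world
veriset annotate  --genes world/sets.gmt --backend scripted:world/transcript.json \
                  --sources world/kb --out results.json
veriset evaluate  --pred results.json --truth world/sets.gmt \
                  --background world/background.txt --obo world/ontology.obo \
                  --out metrics.json
```

The fixture world plants a ground-truth process name for each set, lets
the scripted generation stage emit a perturbed name, and ranks the
planted truth first in the fixture databases. The verification evidence
then steers the modification stage back to the truth. For seed 1 the
run prints (via `results.json` / `metrics.json`):

```
SET001 | putative assembly lipid binding -> assembly lipid binding
SET002 | putative protein division       -> protein division
```

```json
{
  "n_sets": 4,
  "mean_rouge1": 1.0,
  "mean_rouge2": 1.0,
  "mean_rougeL": 0.95,
  "mean_similarity": 0.954
}
```

The three positive sets recover their planted names exactly (per-set
ROUGE-L and similarity 1.0); the one negative control — whose evidence
was withheld — keeps its perturbed name, which depresses the mean
ROUGE-L and similarity. Recall-oriented ROUGE-1/2 stay at 1.0 because
the perturbed name still contains every ground-truth token.

## Layout

| module | contents |
| --- | --- |
| `veriset.types` | `GeneSet`, `Claim`, `EvidenceItem`, `VerificationReport`, `PipelineResult` |
| `veriset.pipeline` | the four-stage cascade and claim extraction/judgment |
| `veriset.backends` / `veriset.prompts` | backend contract, scripted transcripts, stage templates |
| `veriset.sources` | knowledge-source adapters, masking, caching, significance filtering |
| `veriset.ontology` | OBO ingestion, typed-DAG ancestor queries |
| `veriset.metrics` | ROUGE, similarity, percentile, hierarchical, exact-match, Wilson, batching |
| `veriset.fixtures` | deterministic offline worlds and the toy encoder |
| `veriset.io` / `veriset.cli` | GMT/CSV/OBO/JSON I/O and the `veriset` command |
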