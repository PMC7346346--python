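# Methods

This note documents the models, parameters and design choices behind
phenomine, and what its synthetic benchmarks do and do not demonstrate.

## Pipeline overview

The cascade runs in a fixed order; every stage only removes or
re-labels candidates, so stage counts are monotone non-increasing:

1. **Tagging** — drug labels are parsed from a simplified SPL-like XML
   dialect, tokenized, and tagged by the CRF; `AdverseReaction`
   mentions become the drug's ADR term list, deduplicated after
   normalization. By default all label sections are tagged;
   `restrict_sections` confines extraction to named sections.
2. **Homology filter** — BLAST tabular (outfmt 6) hits are kept when
   percent identity is strictly above 30 and E-value strictly below
   1e-4.
3. **Gene mapping** — subject accessions map to gene symbols through a
   two-column TSV; accessions without a symbol (e.g. unnamed
   immunoglobulin chains) are dropped and counted.
4. **PPI expansion** — one hop through a STRING-style network:
   neighbors joined by an edge with combined score ≥ round(1000 ×
   confidence), default 0.7 → 700 inclusive, capped at the 500
   highest-scoring neighbors (ties broken lexicographically). Seed
   genes are always retained and never counted against the cap.
   Expansion is deliberately single-hop; transitive closure would
   dilute the structural-similarity rationale.
5. **Phenotype lookup** — direct gene→HPO links only; obsolete terms
   are excluded, `alt_id`s redirect to primary ids, and no propagation
   up the `is_a` hierarchy is performed (the links file is already
   per-gene; ancestor inflation would only add noise to string
   matching). `is_a` edges are parsed and kept for future use.
6. **Cross-matching** — every (drug, ADR term) × (gene, HPO term) pair
   is scored; the per-term score is the maximum over the HPO name and
   all synonyms, with exact normalized equality short-circuiting to
   1.0. Pairs at or above the threshold (default 0.85) survive.
7. **GO screen** — genes are retained only with at least one
   biological-process annotation whose name contains an immune keyword
   (defaults: "t cell proliferation", "t cell activation", "immune",
   "b cell activation"; configurable, plus an explicit GO-id
   allowlist). This is membership screening, not statistical
   enrichment — there is no background set or p-value.
8. **Triples** — surviving matches collapse to one
   (drug, normalized side effect, gene) triple each, keeping the
   maximum match score and listing all passing GO ids as evidence. The
   final manual literature-confirmation step is out of scope; the
   report says so explicitly.

## The CRF tagger

A standard linear-chain CRF: log-linear state potentials over sparse
binary features plus a first-order transition matrix. Sentences are
the sequence unit — labels never cross sentence boundaries. Choices
that matter:

* **Tagging scheme.** BIEO per entity type. There is no single-token
  tag; a one-token entity is a lone `B-type`, two tokens are
  `B-type E-type`. Decoding repairs ill-formed runs deterministically:
  an orphan `I`/`E` opens (or extends) an entity; entities close at
  `E`, at a tag-type change, or at sequence end. The policy maximizes
  recall and makes `decode(encode(·))` the identity on well-formed
  input.
* **Features** (all configurable via `FeatureTemplateConfig`):
  lowercased token identity in a ±2 window, word shape (collapsed
  case/digit/punctuation pattern), prefixes and suffixes up to length
  3, a bias, and lexicon features `LEX-B/I/E/U` marking the token's
  role inside the longest disorder-lexicon match covering it (greedy
  longest-match, left to right, over lowercased tokens). These are
  conventional BioNLP NER templates; the lexicon feature is the one
  the method leans on.
* **Training.** Full-batch L-BFGS-B (scipy) on the L2-regularized NLL
  (`l2 = 1.0`, `ftol = 1e-6`, `max_iter` 150–200). Gradients are exact
  expected-minus-empirical feature counts from forward–backward;
  log-domain recursions keep scores in ±50 overflow-free. Weights
  start at zero, so training is deterministic; the dev-set entity-level
  micro-F is recorded each iteration and the best-dev weights are
  returned (train micro-F when no dev set is given). Unknown features
  at prediction time are dropped.
* **Ties.** Viterbi breaks ties toward the lower tag index at every
  backtrack step; `O` has index 0, so an all-zero model predicts no
  entities.
* **Evaluation.** A prediction is correct iff type, start and end all
  match an unconsumed gold mention. P, R and F are percentages;
  any 0-denominator metric is 0. Gold mentions whose boundaries fall
  inside a token are snapped outward to the smallest covering token
  run at parse time (logged), which is what makes BIEO alignment
  well-defined.
* **Corpus split.** Document-level, `|train| = round(0.7·N)` half-up,
  shuffled by a seeded RNG.

## Term similarity

The similarity backend is a pluggable `sim(a, b) → [0, 1]` contract.
The default is cosine similarity over padded character-trigram counts
(one boundary marker each side): deterministic, dependency-free, and
symmetric, with `sim = 1` for identical normalized strings and 0 for
strings sharing no trigram. Both-empty compares equal (1); one-empty
scores 0. Normalization lowercases, maps punctuation to spaces and
collapses whitespace. A hook accepts an external word-vector table
(term vector = mean of token vectors, cosine); no embeddings ship with
the package. The 0.85 default threshold admits trivially-variant
spellings (a one-character edit in a ~25-character term scores ≈ 0.87)
while unrelated single-word terms score far below; it is configurable
and echoed in the run report.

## Synthetic data: what it emulates, what it does not

The generators model the *structural* shape of the real resources —
annotated label XML, BLAST tabular, accession maps, STRING edges, OBO
stanzas, gene→phenotype TSV, GAF — with planted ground truth, so every
filter can be exercised and the exact expected output is known by
construction. All randomness flows from one seeded RNG and writes are
ordered, so equal seeds give byte-identical worlds.

* **Label corpus.** Template carrier sentences ("Patients reported X.",
  "Severe X was observed in patients.") with 1–3-token entity terms
  drawn from per-type syllable alphabets; ~30% of lexicon terms also
  appear as non-entity distractors in a distinct carrier context, so
  the lexicon feature alone cannot solve the task. Default study
  conditions: 200 documents, 3 entity types, 30 lexicon terms, 7:3
  split.
* **Screen world.** 5 drugs, 12 genes, 3 planted triples. Each planted
  gene passes every stage; one enters only through a ≥ 700 PPI edge,
  and one planted phenotype name is a single-character-edit variant of
  its ADR term (checked ≥ threshold at generation, regenerated on
  violation) so that non-exact matching is exercised. Six decoy genes
  each fail exactly one stage: identity ≤ 30, E-value ≥ 1e-4, unmapped
  accession, best PPI edge < 700, phenotype dissimilar to every ADR
  term, and no immune biological-process GO term (the last including an
  immune-named annotation outside the P aspect, to exercise the aspect
  restriction). The CRF training corpus for the world is 30 annotated
  documents over the same term pool.

What passing proves: the inference machinery is exact (checked against
enumeration), the filters implement their thresholds, and the cascade
recovers a recoverable signal with precision = recall = 1. What it does
not prove: performance on real clinical language (no misspellings,
anaphora, discontinuous or negated mentions), on real protein
similarity structure, or with real HPO/GO release semantics. Corpus-
level figures from real TAC-2017 / UniProt / STRING / HPO / GO runs
depend on those resources' versions and are not reproducible here.

## Numerical choices and degenerate inputs

* Log-sum-exp everywhere in the forward/backward/partition recursions;
  marginals are exponentiated differences against log Z (position
  marginals sum to 1 within 1e-9).
* Empty sequences are rejected by inference (`T ≥ 1`); empty documents
  predict no mentions; empty intermediate sets flow through the
  pipeline as empty outputs, never errors.
* Character offsets are 0-based half-open throughout; section texts
  join with a single newline and offsets are global to the joined text.
* Strict inequalities on both BLAST thresholds; the E-value screening
  direction is "keep small" (the only direction that screens).
* STRING confidence maps to an inclusive integer cutoff
  (0.7 → ≥ 700), matching the database's own UI semantics.
* `round(ratio·N + 0.5)` (half-up) for the split size, so 1 document at
  ratio 0.7 trains on 1.
* Duplicate/reversed interaction rows collapse to the maximum score;
  self-edges are rejected.
* Gene symbols compare case-sensitively after whitespace trimming.

## Problem sizes

The shipped benchmarks use 200 training documents for the tagger
study, a 30-document training corpus and 12-gene world per cascade
run, and 100 random lattices (T ≤ 6, ≤ 5 tags) for the enumeration
cross-check — sizes at which the planted signal is comfortably
learnable and exhaustive oracles are exact.

## Known limitations

* The tagger scores contiguous mention fragments only; discontinuous
  gold mentions are split into fragments at parse time and scored as
  such, and negation/hedging is not modeled.
* One-hop PPI expansion and direct (non-propagated) HPO links are
  deliberate scope choices, not approximations with error bars.
* The GO screen is keyword membership over annotation names; renamed
  GO terms would require updating keywords or using the id allowlist.
* The trigram backend is a stand-in for whatever embedding similarity
  a user prefers; supply a vector table to change it. The match count
  is sensitive to the threshold, which real deployments should
  calibrate against a labeled sample.
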