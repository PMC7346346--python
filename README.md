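# phenomine

Hybrid phenotype mining for candidate off-target proteins behind
drug adverse reactions.

Immune-checkpoint-blockade antibodies (anti-PD-1/PD-L1 therapeutics)
cause side effects that their intended target does not explain. This
package implements a screening strategy that triangulates *candidate
off-target proteins* by intersecting two independent phenotype views:

* **Drug-centric phenotypes** — adverse drug reactions (ADRs) extracted
  from drug-label text by a linear-chain conditional random field (CRF)
  tagger using the BIEO tagging scheme and a disorder-term lexicon
  feature.
* **Target-centric phenotypes** — phenotypes of proteins reachable from
  the drug by sequence homology (BLAST hits at identity > 30% and
  E-value < 1e-4), one-hop protein–protein-interaction expansion
  (STRING combined score ≥ 700, ≤ 500 neighbors), and Human Phenotype
  Ontology (HPO) gene–phenotype links.

ADR terms and HPO term names are cross-matched by string similarity
(default: padded character-trigram cosine, threshold 0.85, synonyms
included), and matched genes are kept only if they carry immune-related
Gene Ontology biological-process annotations (T cell
proliferation/activation, immune regulation, B cell activation). The
output is a table of candidate **(drug, side effect, gene)** triples
with match scores and GO evidence — a shortlist for manual literature
confirmation, which is deliberately outside the tool.

## The model at the core

The tagger is a standard linear-chain CRF over sentences. With
per-position binary features `f(x, t)` and tag sequence
`y = (y_1 … y_T)`:

```
p(y | x) ∝ exp( Σ_t  w_s[f(x,t), y_t]  +  Σ_t  w_T[y_{t-1}, y_t] )
```

Training maximizes the L2-regularized log-likelihood by full-batch
L-BFGS with exact gradients from forward–backward marginals; decoding
is Viterbi. Entities use BIEO tags (`B-`/`I-`/`E-` per type plus `O`;
a single-token entity is a lone `B-`). Evaluation is exact-match
entity-level precision / recall / F (harmonic mean), per type and
micro-averaged.

## Worked example

Everything runs on synthetic inputs with planted ground truth — no
downloads. Generate a world, point a config at it, and run the
cascade:

```bash
phenomine simulate --seed 11 --out demo/world
# write demo/config.yml with the generated paths (see PipelineConfig)
phenomine run --config demo/config.yml
```

which prints `3 candidate triples -> demo/out` and writes
`demo/out/triples.tsv`:

```
drug       side_effect           gene   hpo_id      score   evidence_go
Abrelimab  silolo tolo           GEN01  HP:0000001  1.0000  GO:0042098
Betrolimab rasi toralo           GEN02  HP:0000002  1.0000  GO:0042110
Cevolumab  losisi loralo rarato  GEN03  HP:0000003  0.8721  GO:0050776
```

Each row is one candidate: the CRF extracted the side-effect term from
that drug's label, the gene survived the homology → PPI → phenotype
cascade, its HPO phenotype matched the ADR term at the shown similarity
(1.0 = exact normalized match; 0.8721 = a near-variant spelling), and
the GO column lists the immune-process evidence that kept the gene.
These three triples are exactly the world's planted ground truth — the
drug and gene names are synthetic stand-ins. `demo/out/report.json`
records the per-stage counts (here 13 deduplicated ADR terms, 10 → 8
BLAST hits, 7 → 8 genes after PPI expansion, 4 matches, 3 retained
genes), and shows every planted decoy dying at its designated stage.

The same pieces are importable directly:

```python
from phenomine import gen_screen_world, run_pipeline, PipelineConfig
world = gen_screen_world("demo/world", seed=11)
triples, report = run_pipeline(PipelineConfig(labels_dir=str(world.labels_dir), ...))
```

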