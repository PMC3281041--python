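# tagdge — tag-based digital gene expression analysis

`tagdge` is a tested, reusable implementation of SAGE-style digital gene
expression (DGE) profiling as used for restriction-anchored tag sequencing
(NlaIII/MmeI protocol): libraries of 21-nt tags — a `CATG` anchor plus the 17
nt that follow it — are cleaned, mapped back to a reference transcriptome, and
compared across conditions with an exact count test. It was built around the
kind of study that profiles an insect gland across developmental stages
(e.g. the silkworm pheromone gland at −72 h, 0 h and 72 h relative to
eclosion), but every stage of the pipeline is generic.

It is a library first: `import tagdge` and compose the stages, or run the thin
`tagdge` CLI for file-to-file use. A protocol simulator with per-tag ground
truth makes the whole pipeline testable without any external data.

## What it computes

- **Virtual tag reference** — every `CATG`+17-nt tag derivable from each
  reference transcript, with gene ownership, ambiguity flags, and lookup
  tolerating one mismatch in the 17-nt variable region.
- **Cleaning** — removal of adaptor-only reads, N-containing reads, and
  copy-number-1 tags (sequencing-error variants), with exact bucket
  accounting.
- **Mapping** — each clean tag classified as gene-mapped (all /
  unambiguous), genome-mapped, or unknown, at best distance (exact preferred
  over one mismatch), with per-gene unambiguous counts.
- **Expression** — TPM (tag copies per million clean tags):
  `TPM_g = copies_g × 10⁶ / clean_total`; copy-number distributions and
  seeded saturation (rarefaction) curves.
- **Differential expression** — the Audic–Claverie exact conditional test:
  for x copies in a library of N₁ tags and y in a library of N₂,

      p(y|x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) ),

  a negative-binomial mass whose tails are regularized incomplete beta
  functions; two-sided p = doubled smaller tail, Benjamini–Hochberg FDR,
  calls at FDR < 0.001 and |log₂ ratio| ≥ 1 (raw-P mode selectable).
- **Enrichment** — upper-tail hypergeometric term enrichment
  p = Σᵢ₌ₘ C(M,i)C(N−M,n−i)/C(N,n) over an annotated background of N genes,
  BH or Bonferroni corrected.
- **Validation arithmetic** — qPCR relative expression as 2^−ΔΔCT against a
  housekeeping reference, and knockdown effects as percent-of-control with
  Student's (or Welch's) t-test.
- **Simulator** — three-stage tag libraries drawn from the 3′-most CATG site
  of each transcript with adaptor-only/N/substitution-error contamination and
  complete per-tag provenance, so calls can be scored against known truth.

## Worked example

```python
from tagdge import (SimConfig, simulate_experiment, clean_raw_tags,
                    build_index, map_library, compute_tpm, call_de_genes,
                    summarize_de)

config = SimConfig(n_genes=2000, n_libraries=2, depth=500_000,
                   de_fraction=0.1, de_fold_change=4.0,
                   error_rate=0.0, adaptor_only_rate=0.0, n_tag_rate=0.0,
                   seed=11)
genes, libraries, truth = simulate_experiment(config)
index = build_index(genes)
expr = {}
for lib_id, raw in libraries.items():
    table, stats = clean_raw_tags(raw)
    mapping = map_library(table, index)
    expr[lib_id] = compute_tpm(mapping.gene_counts, table.clean_total,
                               lib_id, gene_universe=sorted(genes))
calls = call_de_genes(expr["lib1"], expr["lib2"], fdr=0.001, lfc=1.0)
print(summarize_de(calls, "lib1_vs_lib2"))
```

prints

```
DESummary(comparison='lib1_vs_lib2', n_up=93, n_down=70)
```

— 163 genes called differential between the two half-million-tag libraries,
up/down oriented second-over-first. Scoring the same run against the
simulator's truth labels (`tagdge.run_de_recovery`, shown in
`examples/03_differential_expression.py`) gives sensitivity 0.970 on
adequately covered DE genes with empirical FDR 0.000. The other
`examples/*.py` scripts walk through cleaning statistics, mapping and TPM,
saturation, enrichment and the qPCR/knockdown arithmetic, each printing and
explaining its numbers.

The CLI mirrors the stages:

```bash
tagdge simulate --seed 7 --out sim/
tagdge clean --in sim/raw_-72h.tsv --out clean.tsv --stats stats.tsv
tagdge index --reference sim/reference.fasta --out index.tsv
tagdge map --clean clean.tsv --index index.tsv --out counts.tsv
tagdge run --seed 7 --out run/          # everything, with reports
```

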