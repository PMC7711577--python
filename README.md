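# tissueshift

Stochastic genome interrogation for tissue-level expression: quantify how
removing a disease-associated gene set shifts the per-tissue signature of
the remaining gene expression, rank and group the maximally affected
tissues, and summarize many diseases in a single normalized shift matrix.

## The problem

Disease gene lists (from resources such as SFARI or DisGeNet) name genes
*associated* with a condition, but say nothing about which body tissues the
loss of that gene pool would touch most. Given a gene × tissue TPM matrix
(e.g. the GTEx median-TPM release, ~56k genes × 54 tissues), `tissueshift`
asks: if the disease-associated genes are deleted from the genome, which
tissues' expression statistics move the most?

## The statistic

Each TPM count is mapped into [0, 1) by the bounded normalization

    normalized_i = count_i / (count_i + AvgGlobalCount / MaxGlobalCount)

where the global average and maximum are taken over every cell of the
matrix being normalized. Per tissue, the normalized counts across all genes
are treated as a random, memoryless sample and fitted with the exponential
density *y = λ e^{−λx}*; the MLE is the reciprocal sample mean,
λ̂ = n / Σxᵢ. The same fit is run on the matrix with the disease genes
removed (globals recomputed on the reduced matrix by default), and the
shift statistic per tissue is

    Δλ = | λ_full − λ_removed |

Tissues are sorted ascending by Δλ and cut into four median-ranked blocks
(extras go to the low blocks, so 54 tissues give a top block of 13); the
top block is the "maximally affected" tissue group. Alongside λ, the
two-parameter gamma family (shape *a*, scale *b*; the exponential is
*a* = 1) is fitted to place each tissue in a moment space (mean *ab*,
variance *ab²*, skewness 2/√a, excess kurtosis 6/a), and the Earth Mover's
Distance between pre/post-removal histograms gives a shape-sensitive
companion distance. Across diseases, per-row max-normalized Δλ values form
a disease × tissue matrix whose strict 0.8-threshold binarization exposes
overlap patterns between disease groups.

## Worked example

No external data is needed — the built-in generator produces a GTEx-like
matrix with a planted disease signal:

```python
import tissueshift as ts

cfg = ts.SyntheticConfig(
    disease_sets=[ts.DiseaseSpec(name="autism_like", size=100,
                                 target_tissues=["Brain - Amygdala"],
                                 enrichment_fold=50.0)],
    seed=42,
)
em = ts.generate_matrix(cfg)                 # 2000 genes x 54 tissues
gs = ts.generate_gene_sets(cfg)[0]           # 100 planted gene symbols
sr = ts.compute_shift(em, gs)                # remove, refit, rank

tissue, dlam = ts.max_tissue(sr)
print(f"most affected tissue: {tissue}  (Δλ = {dlam:.4f})")
print(ts.top_block(sr)[["tissue_id", "delta_lambda", "group"]].head(5).to_string(index=False))
```

prints

```
most affected tissue: Brain - Amygdala  (Δλ = 0.0319)
                            tissue_id  delta_lambda            group
                     Brain - Amygdala      0.031944              CNS
               Heart - Left Ventricle      0.012599            heart
                  Brain - Hippocampus      0.010559              CNS
Esophagus - Gastroesophageal Junction      0.009525 peripheral_organ
   Brain - Spinal cord (cervical c-1)      0.008946              CNS
```

The planted tissue tops the ranking: its rate moves from λ_full = 1.4195
to λ_removed = 1.4515 (rank 54 of 54, block 4 of 4, EMD 0.015) because the
removed genes were reliably expressed there and only there. Summarizing
and thresholding,

```python
sm = ts.build_summary([sr])          # rows: reference + diseases, cols alphabetical
sorted(sm.on_tissues("autism_like")) # -> ['Brain - Amygdala']
```

the only tissue whose row-normalized Δλ strictly exceeds 0.8 is the
planted one.

The same pipeline runs from the shell on real files:

```sh
tissue-shift synth --out data/                      # or bring your own GCT
tissue-shift run --gct data/expression.gct \
    --gene-set data/geneset_planted.csv \
    --taxonomy data/taxonomy.yaml --out results/
```

which writes `shift_<disease>.tsv`, `topblock_<disease>.tsv`,
`param_space_<disease>.tsv`, `summary.tsv` and `summary_binary.tsv`.

## Layout

- `tissueshift.data_model` — GCT 1.2 and gene-set I/O, tissue taxonomy,
  set algebra (presence confirmation, overlaps, submatrix extraction)
- `tissueshift.mms_normalization` — bounded count normalization and
  strict-local-maximum peak extraction
- `tissueshift.stochastic_fit` — exponential/gamma MLE, gamma moments,
  1-D EMD, Δλ
- `tissueshift.removal_ranking` — removal orchestration, median-ranked
  blocks, top block, most-affected tissue
- `tissueshift.summary_matrix` — disease × tissue normalized Δλ matrix,
  0.8 binarization, overlap reports, gamma moment space
- `tissueshift.synthetic_data` — GTEx-like generator with planted,
  tunable tissue enrichment and structure-recovery experiments

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
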