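# Methods

## Model and procedure

The pipeline treats each tissue's gene expression as a random counting
process. For a gene × tissue TPM matrix the stages are:

1. **Bounded normalization.** Every count is mapped into [0, 1) by
   `x / (x + C)`. The default scale constant is the nested-fraction form
   `C = AvgGlobalCount / MaxGlobalCount` (grand mean over all cells divided
   by grand maximum); the `avg` variant uses `C = AvgGlobalCount` alone,
   the form used for biorhythm waveforms in the micro-movement-spike
   literature. Both variants fix 0 at 0 and saturate towards 1. On
   heavy-tailed TPM data the nested form makes `C` very small (≈1e−5), so
   positive counts normalize close to 1 and the statistic is driven mainly
   by which genes are expressed at all in a tissue; the `avg` variant
   spreads values over the unit interval and weights magnitudes more. Both
   are first-class code paths.
2. **Rate fit.** Per tissue, the normalized series over all genes is fit
   with the exponential density y = λe^{−λx} by maximum likelihood; the
   estimate is closed-form, λ̂ = 1/mean. Optionally (`peaks_only`) the fit
   uses only the strict local maxima of the series — the "spike" events —
   instead of the full series; which of the two a given historical analysis
   used is ambiguous, so neither is asserted as canonical.
3. **Removal.** A disease gene set is first intersected with the matrix
   (absent symbols are reported, never silently dropped), then its rows are
   deleted. The reduced matrix is renormalized with its own global
   statistics by default, treating the post-removal genome as "the" genome;
   `freeze_globals` keeps the full-genome constants for sensitivity
   analysis. An empty effective set leaves the matrix untouched, so every
   downstream shift is exactly zero — this is the reference condition.
4. **Shift and ranking.** Per tissue, Δλ = |λ_full − λ_removed|, plus the
   Earth Mover's Distance between the pre/post normalized-count histograms
   (32 equal-width bins spanning [0, joint max]; the binning is
   configurable, nothing canonical is claimed for 32). Tissues are sorted
   ascending by Δλ (ties broken by tissue name ascending, for determinism)
   and partitioned into `n_blocks` = 4 rank blocks. When T is not divisible
   by the block count, surplus members go to the *low*-rank blocks, so the
   top ("maximally affected") block is the smallest: 54 tissues → block
   sizes [14, 14, 13, 13], top block 13.
5. **Gamma embedding.** The two-parameter gamma family is fit per tissue
   (shape a, scale b); its closed-form moments (mean ab, variance ab²,
   skewness 2/√a, excess kurtosis 6/a) embed each tissue in a moment space
   with Δλ or EMD as a color dimension. The exponential is the a = 1 member,
   so the fitted shape near 1 is a consistency check of the whole family.
6. **Summary.** Per-disease Δλ rows are stacked (columns alphabetical),
   divided by each row's maximum, and binarized at a strict
   `norm > 0.8` threshold. A reference row of exact zeros leads the matrix.
   Group overlap reports intersect the ON sets across disease groups.

## Estimators and numerics

- **Exponential MLE** is analytic (1/mean); no iteration, no tolerance.
- **Gamma MLE** profiles out the scale (b = mean/a) and solves
  log a − ψ(a) = s, with s = log(mean) − mean(log x), by Newton iteration
  from the standard closed-form start a₀ = (3 − s + √((s−3)² + 24s))/(12s).
  Stopping uses both a relative-step and a score criterion (1e−10): on
  nearly constant samples (e.g. saturated normalized counts, shape ~10³–10⁴)
  floating-point cancellation in ψ leaves step jitter around 1e−11 relative,
  so a pure step criterion would stall after the solution is already
  converged. 100 iterations is a hard cap; exceeding it raises a
  convergence error with diagnostics. Zero values lie outside the gamma
  support; by default they are dropped and counted
  (`gamma_zero_policy="drop"`), or replaced by one thousandth of the
  smallest positive value (`"epsilon"`). A zero-variance sample raises an
  error (the likelihood diverges). The kurtosis reported everywhere is the
  *excess* kurtosis 6/a.
- **EMD** on a shared grid is the bin-width-weighted L1 distance between
  the two cumulative histograms — the exact 1-D Wasserstein-1 transport
  cost for mass placed at bin positions; tests verify it against a
  linear-programming transport oracle.
- **Normalization bound.** `x/(x+C)` is clamped at the largest double below
  1 so the half-open [0, 1) invariant survives extreme x/C ratios that
  would otherwise round to exactly 1.
- **Determinism.** The pipeline itself has no randomness; identical inputs
  and configuration reproduce output files byte-for-byte. GCT writing uses
  `%.17g` and reading uses round-trip float parsing, so write→read→write is
  bit-exact.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `eq1_variant` | `avg_over_max` | scale constant of the normalization (see above) |
| `freeze_globals` | off | reuse full-genome normalization constants after removal |
| `peaks_only` | off | fit λ on spike peaks rather than the full series |
| `n_blocks` | 4 | quartile-style rank blocks |
| `n_bins` | 32 | shared histogram bins for the EMD |
| `gamma_zero_policy` | `drop` | zero handling in the gamma fit |
| summary `threshold` | 0.8 | strict cutoff on row-normalized Δλ |

Tie-breaks: equal Δλ sorts by tissue name ascending; the single
most-affected tissue under ties is the alphabetically first among the tied
maxima.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults define the study conditions used throughout the
tests: 2,000 genes over a 54-name GTEx-style tissue panel (13 brain, 2
heart, skeletal muscle, whole blood, peripheral organs — so the taxonomy
patterns fire on realistic names), i.i.d. log-normal(μ=0, σ=2) TPM
baseline, 30% dropout zeros, disease sets of 100 genes (≈5% of the genome,
the order of magnitude of curated disease lists relative to a full
transcriptome). An overlap plan can force an exact number of shared genes
between sets.

Enrichment is multiplicative (`enrichment_fold`, default experiments use
50) on the set's member genes in its target tissues, and those cells are
additionally exempt from dropout: a tissue-enriched gene is both
over-expressed and reliably detected in its tissue. The detection
component matters because under the default normalization positive counts
saturate near 1, so what removal mostly changes in a target tissue is the
fraction of expressed genes; a purely multiplicative boost would be nearly
invisible there and structure recovery would be dominated by dropout
noise. With both components, removing the set provably lowers the target
tissue's mean normalized count more than any other tissue's, which is what
the recovery experiments quantify.

The generator does **not** emulate: correlated expression between related
tissues (real brain regions co-vary strongly), GTEx's gene-symbol
namespace or per-tissue sample counts, library-size artifacts, or
disease-set curation noise. Passing recovery tests therefore show that the
pipeline detects planted single-tissue signal against i.i.d. heavy-tailed
background — not that real disease lists yield the published tissue
rankings, which require the real GTEx matrix and curated lists.

Problem sizes used by the test suite and experiments were chosen to keep
the whole suite interactive (seconds, not minutes): recovery experiments
run 20 replicates at the default scale for the strong-signal condition and
200 replicates at reduced scale (400 genes × 12 tissues) for the null;
both are far above the scale where the effects stabilize.

## Known limitations

- No statistical significance testing of Δλ and no permutation null; Δλ is
  a descriptive effect size. A permutation null over random gene sets of
  matched size would be the natural extension.
- No goodness-of-fit assessment of the exponential assumption; the model
  is a summarization choice, not a claim the data are exponential.
- Gene matching is by canonical (upper-cased) symbol; Ensembl-versioned IDs
  are mapped through the GCT Description column when present. No alias
  resolution is attempted.
- Matrices with extensive duplicate symbols lose all but the first row per
  symbol (warned).
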