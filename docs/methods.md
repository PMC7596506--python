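# Methods

## Model and procedure

`refscreen` treats reference-gene selection as the inverse of
internal-standard normalization. Within one sample, the ratio of any two
genes' expression values is invariant to global, sample-wide scaling
(library size, labeling efficiency, loading differences). A good
reference gene is one whose use as a denominator leaves those ratios
unchanged *between* samples.

For a sample with positive expression vector `A`, the relative
correction factor matrix is `F[i, j] = A_i / A_j`; column `j` is the
sample normalized by gene `j`. For two samples the change-amplitude
matrix is `dF = F1 - F2`. Gene `g`'s stability score is the population
variance (divide by `n`, diagonal zero entry included) of column `g` of
`dF`. Scores are sorted ascending and the top `k` (default 20) reported.
Ties are broken by gene identifier so results are reproducible across
platforms.

At depth `d`, all `C(d, 2)` unordered pairs among the first `d` sample
columns are screened and the per-pair top-`k` gene *sets* intersected.
The intersection is ordered by the sum of the gene's 1-based ranks
across the pairs (ascending, ties by gene id); the reported score for a
depth > 2 result is that rank sum, because sigma^2 values from
different pairs are not commensurable. The intersection can be empty at
high depth. An explicit sample-subset argument generalizes the
"first d columns" convention.

### Matrix orientation and variance axis

The entry definition `F[i, j] = A_i / A_j` follows the column
construction "sample vector divided by gene j" (the matrix is *not*
symmetric). The variance for gene `g` is taken over the column in which
`g` is the **normalizer** (denominator). Both conventions (row vs
column) were examined; the distinction is a single transposition,
isolated in `stability_scores`, and does not change the qualitative
behavior described below.

## What the score actually measures

Column `g` of `dF` contains the ratio changes of *all* genes against
`g`. Two consequences follow:

1. **Expression weighting.** Every entry of column `g` carries a
   `1 / A_g` factor, so the score scales roughly with the inverse square
   of the candidate's expression level. Highly expressed genes are
   systematically favored.
2. **Shared background.** The numerator noise of the other `n - 1`
   genes enters every column. When many genes fluctuate between the two
   samples, this shared term dominates, and a gene's *own* stability
   contributes comparatively little to its score.

Together these mean the screen reliably finds genes that are **both
stable and in the top expression tier** — which is where real reference
genes (ribosomal proteins, ACTB, GAPDH) live — but it cannot single out
a stable gene of average abundance from a noisy background. This is a
property of the ratio-variance statistic itself, not of the
implementation; it is why the synthetic generator plants its stable
genes at high baseline expression (below), and it is the main caveat for
interpreting results on real data.

## Block computation

Matrices larger than `block_size` (default 1000) genes are split into
consecutive blocks in input order; within a block, only the block's own
genes serve as normalizers. Per-gene scores are concatenated across
blocks and sorted globally. This is an approximation of the full
`n x n` computation (a gene's score depends on which genes share its
block); `block_size >= n_genes` gives the exact single-block result and
is what the oracle-equivalence tests exercise. A trailing block of one
gene scores 0 by convention (the variance of its single diagonal entry).

## Preprocessing

Ratios are undefined for nonpositive values, so genes with any value
<= 0 in the samples being compared are dropped before scoring; the count
is logged so the filtering is auditable. Alternatively a constant
pseudocount can be added to the whole matrix (`pseudocount=` /
`--pseudocount`), after which still-nonpositive genes are dropped.

## Normalization

`normalize_by_reference` divides every sample column by its value of the
chosen gene. With `rescale` on (default) values are then multiplied by
the reference's cross-sample mean so the normalized matrix stays on the
input's magnitude — convenient for before/after boxplots; with it off
the values are pure ratios and the operation is idempotent. Whether to
rescale was an open design choice; the default was picked so pre/post QC
plots share a comparable axis. Normalizing by a single gene is only
defensible once that gene's invariance is established, and the CLI
prints a one-line advisory to that effect.

## Overlap and coverage

`pairwise_overlap` screens every unordered sample pair (`C(n, 2)` of
them) and records, per gene, the set of pairs in whose top-`k` list it
appears; a gene's coverage is the fraction of pairs containing it.
`coverage_filter` keeps genes with coverage **strictly** greater than
the threshold (default 0.8). The genes-by-pairs membership table is the
canonical output; the upset-style figure (membership matrix plus
coverage bars, drawn with matplotlib) is a best-effort visual aid and is
not part of the tested numeric surface.

Box-plot summaries use linear interpolation between order statistics for
quartiles and the Tukey 1.5 x IQR rule for outliers; both conventions
are stated because alternatives exist.

## Numerical choices

- All arithmetic is double precision.
- Variance is the population variance (`ddof=0`), diagonal included.
- Scores below `1e-12` are snapped to exactly 0 before ranking: for
  exactly proportional samples the computed sigma^2 is floating-point
  residue (squares of ~1e-16 relative ratio errors), and snapping lets
  the deterministic gene-id tie-break apply instead of noise ordering.
  Genuine sigma^2 values of interest are many orders of magnitude
  larger.
- "Proportional implies zero score" assertions use an absolute
  tolerance of 1e-10.

## Synthetic data generator

`SyntheticSpec` / `generate` produce matrices with known ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_samples` | 1000, 4 | matrix shape |
| `n_stable` | 20 | planted stable genes |
| `stable_cv` | 0.01 | CV of multiplicative noise on planted genes |
| `unstable_cv` | 0.30 | CV of per-sample fold factors on background genes |
| `sample_scale_range` | (0.5, 2.0) | per-sample global scale factors (log-uniform) |
| `base_expression_range` | (10, 1000) | background baselines (log-uniform) |
| `stable_expression_range` | (2000, 5000) | planted-gene baselines (log-uniform) |

Each value is `baseline[g] * scale[s] * noise[g, s]` with mean-1
lognormal noise (expression is positive and the score is ratio-based;
CV parameterization keeps effect sizes interpretable). Ground truth is
"proportional across samples up to `stable_cv` noise" — exactly the
property the score targets. Planted genes sit above the background's
expression range because real reference genes are high-abundance
transcripts and because, per the expression-weighting property above,
that is the regime in which the statistic can separate them; with
planted baselines drawn from the background range the screen does *not*
recover them, at any baseline width we examined.

The generator emulates global scaling differences, stable/unstable
partitioning and multiplicative noise. It does **not** emulate
count-based sequencing noise (mean-variance relationships), probe
effects, correlated gene families, or condition-dependent regulation —
so passing recovery tests demonstrate the algorithm's behavior under its
own assumptions, not performance on any particular real platform.

## Problem sizes

The test suite and the acceptance script run on matrices of 100–1000
genes and 2–12 samples with single-block (exact) scoring; these sizes
exercise every code path, including the blockwise path (tested at
250 genes with 100-gene blocks). The algorithm itself is O(n * block_size)
per pair in memory and time and handles full-transcriptome inputs.

## Known limitations

- A stable but lowly expressed gene will not rank well (expression
  weighting).
- Blockwise scores depend on gene input order; use
  `block_size >= n_genes` when exactness matters and memory allows.
- Depth uses the first `d` sample columns by default; which samples are
  chosen changes the result (pass `samples=` to control it).
- The rank-sum ordering of a depth > 2 intersection is a pragmatic
  aggregate; it has no variance interpretation.
- No probe-to-gene-symbol annotation, no multi-gene normalization
  factors, and no geNorm/NormFinder/BestKeeper statistics are computed.
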