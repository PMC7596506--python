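# refscreen

Screening endogenous reference genes (internal controls / housekeeping
genes) from gene-expression matrices — bulk microarray, RT-PCR panels, or
sequencing-derived tables.

Normalizing expression data against an internal reference gene assumes
that gene is expressed at a constant level across samples. Tools such as
geNorm, NormFinder and BestKeeper evaluate a *pre-chosen* shortlist of
candidates; `refscreen` instead inverts the normalization process and
scores **every** gene in the matrix, so no candidate list is needed.

## The score

For a sample with expression vector $A = (A_1, \dots, A_n)$, form the
relative correction factor matrix

$$F[i,j] = A_i / A_j,$$

whose column $j$ is the whole sample normalized by gene $j$. For two
samples, the change-amplitude matrix is $\Delta F = F_1 - F_2$; it is
identically zero when the samples differ only by a global scale factor.
Gene $g$ is scored by the population variance $\sigma^2_g$ of column $g$
of $\Delta F$ — how much the rest of the transcriptome appears to move
when $g$ is used as the internal standard. Low $\sigma^2$ = stable
candidate. The top 20 genes (configurable) are reported.

At computational depth $d$, every unordered pair among the first $d$
samples is screened ($\binom{d}{2}$ pairs) and the per-pair top-20 sets
are intersected, ordered by summed per-pair rank. Large matrices are
processed in blocks of 1000 genes. Because column $g$ carries a
$1/A_g$ weight, the score favors genes that are both stable *and* highly
expressed — consistent with real reference genes (ribosomal proteins,
ACTB, GAPDH), but see `docs/methods.md` for the implications.

## Worked example

Simulate a 500-gene, 4-sample matrix with 5 planted stable genes, then
screen it at depth 3:

```sh
$ refscreen simulate --n-genes 500 --n-stable 5 --seed 11 \
      -o demo.tsv --truth-output demo_truth.txt
wrote 500x4 matrix (5 planted stable genes) to demo.tsv

$ refscreen find demo.tsv --depth 3 -o demo_rank.tsv
wrote 13 candidates to demo_rank.tsv
wrote pair membership table to demo_rank.membership.tsv

$ head -8 demo_rank.tsv
# pairs=S1|S2;S1|S3;S2|S3
# k=20 score=rank_sum
gene_id	score
G010	4
G123	5
G081	9
G076	12
G238	15
```

Thirteen genes survive the intersection of the three pairwise top-20
lists; the score column is each gene's summed rank across the three
pairs (lower = more consistently stable). The first five candidates are
exactly the planted stable genes (`demo_truth.txt` lists G010, G076,
G081, G123, G238). Coverage across *all* six sample pairs:

```sh
$ refscreen overlap demo.tsv --out-prefix demo_ov
6 sample pairs; 10 genes above 80% coverage: G010, G049, G076, G081, ...
```

All five planted genes sit above the 80% pair-coverage threshold.
`refscreen normalize --ref-gene G010 ...` then divides every sample by
its value of the chosen reference (with a rescale so magnitudes stay
plot-comparable), and `refscreen summary --plot ...` draws the
before/after boxplot + density QC views.

The same operations are available as a library:

```python
from refscreen import read_expression_table, find_reference_genes
expr = read_expression_table("demo.tsv")
ranking = find_reference_genes(expr, depth=2)   # [(gene_id, sigma^2), ...]
```

GEO series-matrix files are read directly with
`refscreen find --series-matrix <file>` (probe identifiers are kept
as-is; no probe-to-symbol conversion is performed).

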