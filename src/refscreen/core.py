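"""Ratio-variance stability scoring and reference-gene screening.

The method inverts internal-standard normalization.  For one sample with
expression vector ``A = (A_1 .. A_n)``, the relative correction factor
matrix is ``F[i, j] = A_i / A_j`` -- column *j* is the whole sample
normalized by gene *j*.  For two samples the change-amplitude matrix is
``dF = F1 - F2``; if the samples are proportional (pure global scaling),
``dF`` is identically zero.  Gene *g* is scored by the population variance
of column *g* of ``dF`` (the column in which *g* is the normalizer): the
lower the variance, the less the rest of the transcriptome appears to move
when *g* is used as the internal standard, hence the better a reference
candidate *g* is.

Because column *g* is weighted by ``1 / A_g``, the score favors genes that
are both stable *and* highly expressed.  That matches practice -- commonly
used reference genes (ribosomal proteins, ACTB, GAPDH) sit in the top
expression tier -- but it means a stable, lowly expressed gene will not
rank well; see the package methods note.

For large matrices the genes are split into consecutive blocks (default
1000 genes) and each block is scored against its own genes only; scores
are then concatenated and sorted.  ``block_size >= n_genes`` gives the
exact single-block computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "RelativeFactorMatrix",
    "DeltaFactorMatrix",
    "StabilityScores",
    "CandidateRanking",
    "relative_factor_matrix",
    "delta_factor_matrix",
    "stability_scores",
    "screen_pair",
    "find_reference_genes",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 20
DEFAULT_BLOCK_SIZE = 1000

# sigma^2 below this is floating-point residue of an exactly proportional
# pair (squares of ~1e-16 relative ratio errors); snapped to 0 so the
# deterministic gene-id tie-break applies instead of noise ordering
ZERO_SCORE_TOL = 1e-12


@dataclass
class RelativeFactorMatrix:
    """All pairwise within-sample expression ratios: entries[i, j] = v_i / v_j."""

    gene_ids: list[str]
    entries: np.ndarray = field(repr=False)


@dataclass
class DeltaFactorMatrix:
    """Elementwise difference of two samples' ratio matrices (F1 - F2)."""

    gene_ids: list[str]
    entries: np.ndarray = field(repr=False)


@dataclass
class StabilityScores:
    """Per-gene ratio-change variances (sigma^2) for one sample pair.

    Lower is more stable.  ``pair`` records which two samples were compared.
    """

    gene_ids: list[str]
    scores: np.ndarray = field(repr=False)
    pair: tuple[str, str]


@dataclass
class CandidateRanking:
    """Ordered reference-gene candidates.

    ``entries`` is ascending by score.  For a single sample pair the score
    is sigma^2; for a depth-wise intersection it is the sum of the gene's
    ranks (1-based) across the per-pair lists, since per-pair sigma^2
    values are not commensurable.  ``pairs`` records provenance.
    """

    entries: list[tuple[str, float]]
    k: int
    pairs: list[tuple[str, str]]
    score_kind: str = "sigma2"  # or "rank_sum"

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def relative_factor_matrix(
    sample: Sequence[float] | np.ndarray,
    gene_ids: Sequence[str] | None = None,
) -> RelativeFactorMatrix:
    """Pairwise ratio matrix of one sample's expression vector.

    ``entries[i, j] = sample[i] / sample[j]`` -- column *j* is the sample
    normalized by gene *j*.  All values must be strictly positive.
    """
    v = np.asarray(sample, dtype=float)
    if v.ndim != 1:
        raise ValueError("sample must be a 1-D vector")
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive expression at gene index {bad[0]} "
            f"(value {v[bad[0]]!r}); ratios are undefined"
        )
    ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(v.size)]
    if len(ids) != v.size:
        raise ValueError("gene_ids length does not match sample length")
    return RelativeFactorMatrix(ids, v[:, None] / v[None, :])


def delta_factor_matrix(
    f1: RelativeFactorMatrix, f2: RelativeFactorMatrix
) -> DeltaFactorMatrix:
    """Change-amplitude matrix F1 - F2 for two samples of the same genes."""
    if f1.gene_ids != f2.gene_ids:
        raise ValueError("factor matrices are over different gene sets")
    if f1.entries.shape != f2.entries.shape:
        raise ValueError("factor matrices have different shapes")
    return DeltaFactorMatrix(list(f1.gene_ids), f1.entries - f2.entries)


def stability_scores(
    delta: DeltaFactorMatrix, pair: tuple[str, str] = ("sample_1", "sample_2")
) -> StabilityScores:
    """Per-gene sigma^2: population variance of each gene's normalizer column.

    Gene *g*'s score is the variance (divide by n, zero diagonal entry
    included) of column *g* of the change-amplitude matrix -- the n ratio
    changes observed when *g* is the internal standard.
    """
    d = delta.entries
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("delta matrix must be square")
    return StabilityScores(list(delta.gene_ids), d.var(axis=0, ddof=0), pair)


def _pair_scores_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sigma^2 for one block: vectorized Eqs. of the ratio-variance score."""
    d = a[:, None] / a[None, :] - b[:, None] / b[None, :]
    return d.var(axis=0, ddof=0)


# ----------------------------------------------------------------------
# screening
# ----------------------------------------------------------------------

def _positive_filter(
    expr: ExpressionMatrix,
    columns: Sequence[int],
    pseudocount: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep genes strictly positive in the given sample columns.

    Returns (kept gene row indices, values array to score -- possibly
    shifted by ``pseudocount``).  Drops are logged so the implicit
    preprocessing is auditable.
    """
    values = expr.values
    if pseudocount is not None:
        values = values + float(pseudocount)
    ok = (values[:, list(columns)] > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "dropped %d/%d genes with nonpositive values in samples %s",
            n_dropped, expr.n_genes, [expr.sample_ids[c] for c in columns],
        )
    return np.flatnonzero(ok), values


def _ranked_order(scores: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Ascending by score, ties broken by gene id (deterministic)."""
    return np.lexsort((np.asarray(gene_ids, dtype=object), scores))


def screen_pair(
    expr: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    k: int = DEFAULT_TOP_K,
    block_size: int = DEFAULT_BLOCK_SIZE,
    pseudocount: float | None = None,
    _full: bool = False,
) -> CandidateRanking:
    """Rank reference-gene candidates from one pair of samples.

    Genes are processed in consecutive blocks of ``block_size`` (each gene
    is scored against the genes of its own block); per-gene sigma^2 values
    are concatenated, sorted ascending with ties broken by gene id, and
    the top ``k`` returned.  ``block_size >= n_genes`` gives the exact
    whole-matrix computation.

    Genes with any nonpositive value in the two samples are dropped first
    (or shifted if ``pseudocount`` is given).  With ``_full=True`` all
    scored genes are returned instead of the top k (used by the overlap
    and intersection machinery).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    ia, ib = expr.sample_index(sample_a), expr.sample_index(sample_b)
    keep, values = _positive_filter(expr, (ia, ib), pseudocount)
    if keep.size < 2:
        raise ValueError(
            f"fewer than 2 genes with positive expression in samples "
            f"{sample_a!r} and {sample_b!r}"
        )
    a_full, b_full = values[keep, ia], values[keep, ib]
    gene_ids = [expr.gene_ids[i] for i in keep]

    scores = np.empty(keep.size)
    for start in range(0, keep.size, block_size):
        stop = min(start + block_size, keep.size)
        if stop - start == 1:
            # a trailing singleton block has only itself as normalizer
            scores[start] = 0.0
        else:
            scores[start:stop] = _pair_scores_block(
                a_full[start:stop], b_full[start:stop]
            )

    scores[scores < ZERO_SCORE_TOL] = 0.0
    order = _ranked_order(scores, gene_ids)
    if not _full:
        order = order[: min(k, order.size)]
    entries = [(gene_ids[i], float(scores[i])) for i in order]
    return CandidateRanking(entries, k, [(sample_a, sample_b)], "sigma2")


def find_reference_genes(
    expr: ExpressionMatrix,
    depth: int,
    k: int = DEFAULT_TOP_K,
    block_size: int = DEFAULT_BLOCK_SIZE,
    samples: Sequence[str] | None = None,
    pseudocount: float | None = None,
) -> CandidateRanking:
    """Screen reference genes at a given computational depth.

    Depth *d* screens every unordered pair among the first *d* sample
    columns (``C(d, 2)`` pairs) -- or among ``samples`` if given -- and
    intersects the per-pair top-``k`` gene sets.  Depth 2 is a single
    pairwise screen.  The deeper the screen, the fewer (possibly zero)
    genes survive the intersection.

    The intersection is ordered by the sum of each gene's 1-based ranks
    across the per-pair lists (ascending; ties by gene id), so genes that
    rank high in every pair come first.
    """
    if samples is None:
        pool = expr.sample_ids
    else:
        pool = [str(s) for s in samples]
        for s in pool:
            expr.sample_index(s)  # validate early
    if not 2 <= depth <= len(pool):
        raise ValueError(
            f"depth {depth} is invalid: the number of samples selected "
            f"cannot be fewer than 2 or more than the number of samples "
            f"({len(pool)})"
        )
    selected = pool[:depth]
    pairs = list(combinations(selected, 2))
    rankings = [
        screen_pair(expr, a, b, k=k, block_size=block_size, pseudocount=pseudocount)
        for a, b in pairs
    ]
    logger.info("screened %d sample pairs at depth %d", len(pairs), depth)

    if depth == 2:
        return rankings[0]

    rank_maps = [
        {g: r for r, (g, _) in enumerate(rk.entries, start=1)} for rk in rankings
    ]
    common = set(rank_maps[0])
    for m in rank_maps[1:]:
        common &= set(m)
    ordered = sorted(common, key=lambda g: (sum(m[g] for m in rank_maps), g))
    entries = [(g, float(sum(m[g] for m in rank_maps))) for g in ordered]
    return CandidateRanking(entries, k, pairs, "rank_sum")
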