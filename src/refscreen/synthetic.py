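"""Synthetic expression matrices with planted reference genes.

The generator emulates the structure the ratio-variance screen assumes:

* per-sample global scaling (library size / labeling efficiency
  differences), drawn from ``sample_scale_range``;
* a planted subset of *stable* genes that are proportional across samples
  up to small multiplicative noise (``stable_cv``);
* a background of *unstable* genes whose per-sample lognormal fold
  factors carry substantial noise (``unstable_cv``).

Stable genes are planted at high baseline expression
(``stable_expression_range``, above the background
``base_expression_range``), mirroring real data: the genes used as
internal standards -- ribosomal proteins, ACTB, GAPDH -- sit in the top
expression tier.  This is also the regime in which the ratio-variance
score, which weights each candidate by its inverse squared expression,
can separate stable from unstable genes; see the methods note.

All noise is multiplicative lognormal (expression is positive and the
score is ratio-based); CV parameterization keeps effect sizes
interpretable.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic-matrix generator.

    ``sample_scales`` may be an explicit per-sample sequence of positive
    factors; otherwise one factor per sample is drawn log-uniformly from
    ``sample_scale_range``.  Baselines are drawn log-uniformly from
    ``base_expression_range`` (background genes) and
    ``stable_expression_range`` (planted stable genes).
    """

    n_genes: int = 1000
    n_samples: int = 4
    n_stable: int = 20
    stable_cv: float = 0.01
    unstable_cv: float = 0.3
    sample_scales: tuple[float, ...] | None = None
    sample_scale_range: tuple[float, float] = (0.5, 2.0)
    base_expression_range: tuple[float, float] = (10.0, 1000.0)
    stable_expression_range: tuple[float, float] = (2000.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.n_stable <= self.n_genes:
            raise ValueError("n_stable must be in [0, n_genes]")
        if self.stable_cv < 0 or self.unstable_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        for name in ("sample_scale_range", "base_expression_range",
                     "stable_expression_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if self.sample_scales is not None:
            scales = tuple(float(s) for s in self.sample_scales)
            if len(scales) != self.n_samples:
                raise ValueError("sample_scales length must equal n_samples")
            if any(s <= 0 for s in scales):
                raise ValueError("sample scales must be positive")
            self.sample_scales = scales


def _lognormal_cv(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal factors with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _log_uniform(
    rng: np.random.Generator, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, set[str]]:
    """Generate a synthetic matrix and the set of planted stable gene ids.

    Each value is ``baseline[g] * scale[s] * noise[g, s]`` where the noise
    factor has CV ``stable_cv`` for planted genes and ``unstable_cv`` for
    the rest.  In the noise-free limit every sample is exactly
    proportional to every other.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes - 1)) if spec.n_genes > 1 else 1
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j + 1}" for j in range(spec.n_samples)]

    base = _log_uniform(rng, *spec.base_expression_range, spec.n_genes)
    stable_idx = np.sort(
        rng.choice(spec.n_genes, size=spec.n_stable, replace=False)
    )
    base[stable_idx] = _log_uniform(
        rng, *spec.stable_expression_range, spec.n_stable
    )

    if spec.sample_scales is not None:
        scales = np.asarray(spec.sample_scales, dtype=float)
    else:
        scales = _log_uniform(rng, *spec.sample_scale_range, spec.n_samples)

    values = np.empty((spec.n_genes, spec.n_samples))
    stable_mask = np.zeros(spec.n_genes, dtype=bool)
    stable_mask[stable_idx] = True
    for j in range(spec.n_samples):
        noise = _lognormal_cv(rng, spec.unstable_cv, spec.n_genes)
        noise[stable_mask] = _lognormal_cv(rng, spec.stable_cv, spec.n_stable)
        values[:, j] = base * scales[j] * noise

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = {gene_ids[i] for i in stable_idx}
    return expr, truth
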