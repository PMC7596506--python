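"""Candidate overlap across all sample pairs, and distribution QC summaries.

Screening each of the ``C(n_samples, 2)`` sample pairs yields one top-k
candidate list per pair.  A gene's *coverage* is the fraction of pairs in
whose list it appears; genes with high coverage are stable regardless of
which samples are compared and are the strongest reference candidates.
This is the computation an upset plot of the per-pair candidate sets
visualizes.

:func:`sample_distribution_summary` provides the per-sample box-plot /
density numbers used to judge, before and after normalization, how far
apart the samples' overall expression distributions sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_BLOCK_SIZE, DEFAULT_TOP_K, screen_pair
from .matrix import ExpressionMatrix

__all__ = [
    "OverlapTable",
    "pairwise_overlap",
    "coverage_filter",
    "emit_upset_data",
    "sample_distribution_summary",
    "plot_distributions",
]


@dataclass
class OverlapTable:
    """Per-gene membership in the top-k lists of every sample pair."""

    pairs: list[tuple[str, str]]
    membership: dict[str, frozenset[int]]  # gene -> indices into pairs
    k: int

    @property
    def coverage(self) -> dict[str, float]:
        """Fraction of sample pairs whose top-k list contains each gene."""
        n = len(self.pairs)
        return {g: len(idx) / n for g, idx in self.membership.items()}

    def to_dataframe(self) -> pd.DataFrame:
        """Genes x pairs boolean membership table (genes sorted by coverage)."""
        cols = [f"{a}|{b}" for a, b in self.pairs]
        genes = sorted(
            self.membership, key=lambda g: (-len(self.membership[g]), g)
        )
        data = np.zeros((len(genes), len(cols)), dtype=int)
        for r, g in enumerate(genes):
            for c in self.membership[g]:
                data[r, c] = 1
        return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=cols)


def pairwise_overlap(
    expr: ExpressionMatrix,
    k: int = DEFAULT_TOP_K,
    block_size: int = DEFAULT_BLOCK_SIZE,
    pseudocount: float | None = None,
) -> OverlapTable:
    """Screen every unordered sample pair and record top-k membership."""
    pairs = list(combinations(expr.sample_ids, 2))
    membership: dict[str, set[int]] = {}
    for idx, (a, b) in enumerate(pairs):
        ranking = screen_pair(
            expr, a, b, k=k, block_size=block_size, pseudocount=pseudocount
        )
        for gene in ranking.genes:
            membership.setdefault(gene, set()).add(idx)
    frozen = {g: frozenset(s) for g, s in membership.items()}
    return OverlapTable(pairs, frozen, k)


def coverage_filter(table: OverlapTable, min_coverage: float = 0.8) -> list[str]:
    """Genes present in strictly more than ``min_coverage`` of the pair lists.

    Sorted by coverage descending, ties by gene id.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    cov = table.coverage
    hits = [g for g, c in cov.items() if c > min_coverage]
    return sorted(hits, key=lambda g: (-cov[g], g))


def emit_upset_data(
    table: OverlapTable, path: str | Path, plot_path: str | Path | None = None
) -> pd.DataFrame:
    """Write the genes x pairs membership table (TSV of 0/1).

    If ``plot_path`` is given, additionally render an upset-style figure
    (membership matrix plus per-gene coverage bars).  The numeric table is
    the canonical output; the figure is a best-effort visual aid.
    """
    df = table.to_dataframe()
    df.to_csv(path, sep="\t")
    if plot_path is not None:
        _render_upset(table, df, plot_path)
    return df


def _render_upset(
    table: OverlapTable, df: pd.DataFrame, plot_path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if df.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.set_axis_off()
        ax.text(0.5, 0.5, "no candidate genes", ha="center", va="center")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        return

    n_genes, n_pairs = df.shape
    cov = df.sum(axis=1) / n_pairs
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(max(6, 0.35 * n_genes), 6),
        sharex=True, height_ratios=[1, 2],
    )
    x = np.arange(n_genes)
    ax_bar.bar(x, cov.to_numpy(), color="#4472a8")
    ax_bar.axhline(0.8, color="firebrick", lw=0.8, ls="--")
    ax_bar.set_ylabel("pair coverage")
    ax_bar.set_ylim(0, 1.02)
    ys, xs = np.nonzero(df.to_numpy().T)
    ax_mat.scatter(xs, ys, s=14, color="#333333")
    ax_mat.set_yticks(np.arange(n_pairs))
    ax_mat.set_yticklabels(df.columns, fontsize=6)
    ax_mat.set_xticks(x)
    ax_mat.set_xticklabels(df.index, rotation=90, fontsize=6)
    ax_mat.set_ylabel("sample pair")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)


def sample_distribution_summary(expr: ExpressionMatrix) -> pd.DataFrame:
    """Box-plot statistics per sample.

    Returns one row per sample with min, lower quartile, median, upper
    quartile, max, IQR and the Tukey outlier count (points beyond
    1.5 x IQR from the quartiles).  Quartiles use linear interpolation
    between order statistics.
    """
    rows = []
    for j, sid in enumerate(expr.sample_ids):
        v = expr.values[:, j]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        outliers = int(((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)).sum())
        rows.append(
            {
                "sample_id": sid,
                "min": v.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": v.max(),
                "iqr": iqr,
                "n_outliers": outliers,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def plot_distributions(expr: ExpressionMatrix, path: str | Path) -> None:
    """Side-by-side boxplot and density plot of every sample's values.

    The QC view used to compare samples' overall expression distributions
    before and after normalization.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, (ax_box, ax_den) = plt.subplots(1, 2, figsize=(10, 4))
    cols = [expr.values[:, j] for j in range(expr.n_samples)]
    ax_box.boxplot(cols, tick_labels=expr.sample_ids)
    ax_box.set_ylabel("expression")
    ax_box.tick_params(axis="x", rotation=90, labelsize=7)
    for v, sid in zip(cols, expr.sample_ids):
        if np.ptp(v) > 0:
            grid = np.linspace(v.min(), v.max(), 200)
            ax_den.plot(grid, gaussian_kde(v)(grid), lw=1, label=sid)
    ax_den.set_xlabel("expression")
    ax_den.set_ylabel("density")
    if expr.n_samples <= 12:
        ax_den.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
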