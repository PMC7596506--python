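"""Core in-memory container for gene-expression tables.

An :class:`ExpressionMatrix` is a genes x samples table of expression
values (counts, intensities, or normalized signal -- whatever the platform
produced) with unique gene identifiers and sample labels.  The screening
algorithm works on within-sample expression *ratios*, so values must be
strictly positive; genes violating that are filtered at screening time,
not here (construction only requires finite numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    gene_ids
        Unique gene/probe identifiers, one per row.
    sample_ids
        Unique sample labels, one per column.
    values
        ``(n_genes, n_samples)`` float array of expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows of values"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        if n_samples < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    # -- shape ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- access --------------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(
                f"unknown sample id {sample_id!r}; "
                f"available: {', '.join(self.sample_ids)}"
            ) from None

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def sample(self, sample_id: str) -> np.ndarray:
        """Expression vector of one sample (a column)."""
        return self.values[:, self.sample_index(sample_id)]

    # -- conversion ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by gene id, one column per sample."""
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), self.values.copy()
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None
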