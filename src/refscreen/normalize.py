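"""Single-reference-gene normalization of an expression matrix.

Dividing every sample by its value of a chosen reference gene removes
per-sample global scaling exactly when the reference is truly constant
-- this is the operation whose inversion underlies the screening score.
By default the ratios are rescaled by the reference gene's cross-sample
mean so the normalized matrix stays on the magnitude of the input (useful
for before/after boxplots); with ``rescale=False`` plain ratios are
returned and the operation is idempotent.

Normalizing by a *single* gene is only defensible when that gene's
invariance has been demonstrated; callers are expected to pair this with
the screening module (the CLI prints a one-line advisory).
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["normalize_by_reference"]


def normalize_by_reference(
    expr: ExpressionMatrix, ref_gene: str, rescale: bool = True
) -> ExpressionMatrix:
    """Divide every sample column by its expression of ``ref_gene``.

    After normalization the reference gene's row is constant across
    samples.  With ``rescale`` (default) all values are multiplied by the
    reference's arithmetic mean across samples, preserving the overall
    magnitude; without it values are pure ratios to the reference.
    """
    g = expr.gene_index(ref_gene)
    ref_row = expr.values[g, :]
    bad = np.flatnonzero(ref_row <= 0)
    if bad.size:
        raise ValueError(
            f"reference gene {ref_gene!r} has nonpositive expression in "
            f"sample {expr.sample_ids[bad[0]]!r}; cannot normalize"
        )
    normalized = expr.values / ref_row[None, :]
    if rescale:
        normalized = normalized * ref_row.mean()
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), normalized)
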