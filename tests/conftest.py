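import numpy as np
import pytest

from refscreen import ExpressionMatrix, SyntheticSpec, generate


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with easily hand-checked ratios."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["A", "B"],
        np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]),
    )


@pytest.fixture
def proportional_matrix() -> ExpressionMatrix:
    """4 samples that are exact global rescalings of one base profile."""
    rng = np.random.default_rng(42)
    base = rng.uniform(5, 500, 60)
    scales = np.array([1.0, 0.5, 2.0, 3.5])
    return ExpressionMatrix(
        [f"g{i:02d}" for i in range(60)],
        ["S1", "S2", "S3", "S4"],
        base[:, None] * scales[None, :],
    )


@pytest.fixture(scope="session")
def planted() -> tuple:
    """The default synthetic study matrix: 1000 genes, 4 samples, 20 planted."""
    return generate(SyntheticSpec(seed=1))


def oracle_pair_scores(a, b) -> list[float]:
    """Naive two-loop reference for the ratio-variance score.

    Written independently of the vectorized path: explicit ratios per gene
    pair, explicit population variance per normalizer column.
    """
    n = len(a)
    out = []
    for g in range(n):
        col = [a[i] / a[g] - b[i] / b[g] for i in range(n)]
        mean = sum(col) / n
        out.append(sum((x - mean) ** 2 for x in col) / n)
    return out
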