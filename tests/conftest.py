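import numpy as np
import pytest

from sastra import ExpressionMatrix
from sastra.decompose import SADecomposition


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 samples x 1 analyte with linear values 1..4 (median 2.5)."""
    return ExpressionMatrix(
        ["s1", "s2", "s3", "s4"], ["EGFR"],
        np.array([[1.0], [2.0], [3.0], [4.0]]), scale="linear",
    )


def make_matrix(values, scale="log", prefix=("s", "a")) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        [f"{prefix[0]}{i + 1}" for i in range(n)],
        [f"{prefix[1]}{j + 1}" for j in range(m)],
        values, scale=scale,
    )


def make_decomposition(G, lambdas, baseline_pattern=None, baseline_weights=None,
                       singular_values=None) -> SADecomposition:
    """Hand-crafted decomposition for unit tests of downstream stages."""
    G = np.asarray(G, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    m, r = G.shape
    n = lambdas.shape[0]
    if baseline_pattern is None:
        baseline_pattern = np.ones(m) / np.sqrt(m)
    if baseline_weights is None:
        baseline_weights = np.full(n, 5.0 * np.sqrt(m))
    if singular_values is None:
        singular_values = np.sort(np.linalg.norm(lambdas, axis=0))[::-1]
    return SADecomposition(
        sample_ids=[f"s{k + 1}" for k in range(n)],
        analyte_ids=[f"a{i + 1}" for i in range(m)],
        baseline_pattern=np.asarray(baseline_pattern, dtype=float),
        baseline_weights=np.asarray(baseline_weights, dtype=float),
        G=G, lambdas=lambdas,
        singular_values=np.asarray(singular_values, dtype=float),
    )
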