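"""Surprisal-analysis decomposition of a log-expression matrix.

The model writes the natural-log expression of analyte ``i`` in sample ``k``
as a constraint-free steady-state term minus a sum of unbalanced-process
terms::

    ln X_i(k) = ln X_i^0(k) - sum_a  G_{ia} * lambda_a(k)

Each process ``a`` couples an analyte participation-weight vector ``G[:, a]``
(unit Euclidean norm) with per-sample amplitudes ``lambda[:, a]``. The
factorisation is the exact singular value decomposition of the ln-matrix:
the rank-one component with the largest singular value is designated the
steady-state/baseline term, and the remaining components, in descending
singular value, are the candidate unbalanced processes. Singular values are
absorbed into the amplitudes so that amplitudes are comparable across
processes.

Conventions (the decomposition of a given matrix is then unique and
deterministic):

* the baseline is oriented so its per-sample weights have positive mean;
* each G column is oriented so its largest-magnitude element is positive,
  with the amplitude column flipped in tandem (the product is unchanged);
* exactly tied singular values are ordered by the lexicographically smaller
  G column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["SADecomposition", "surprisal_decompose", "reconstruct", "process_signature_similarity"]

_RANK_TOL = 1e-12  # relative singular-value cutoff for rank deficiency


@dataclass
class SADecomposition:
    """Steady-state baseline plus candidate unbalanced processes.

    Attributes
    ----------
    baseline_pattern
        Unit-norm analyte pattern of the steady-state term.
    baseline_weights
        Per-sample weight of the steady-state term (singular value absorbed);
        near-constant across samples on data dominated by a common baseline.
    G
        Analytes x processes participation weights; columns unit-norm,
        mutually orthogonal.
    lambdas
        Samples x processes amplitudes; ``lambdas[k, a]`` is the importance
        of process ``a`` in sample ``k``.
    singular_values
        Singular value of each process component, non-increasing.
    """

    sample_ids: list[str]
    analyte_ids: list[str]
    baseline_pattern: np.ndarray
    baseline_weights: np.ndarray
    G: np.ndarray
    lambdas: np.ndarray
    singular_values: np.ndarray

    @property
    def n_candidate_processes(self) -> int:
        return self.G.shape[1]

    @property
    def baseline_log_levels(self) -> np.ndarray:
        """Sample-independent steady-state log levels (pattern x mean weight)."""
        return self.baseline_pattern * float(np.mean(self.baseline_weights))

    def baseline_term(self) -> np.ndarray:
        return np.outer(self.baseline_weights, self.baseline_pattern)

    def log_matrix(self, n_processes: int | None = None) -> np.ndarray:
        """Reconstructed ln-matrix from baseline + the first ``n_processes``."""
        n = self.n_candidate_processes if n_processes is None else n_processes
        if not 0 <= n <= self.n_candidate_processes:
            raise ValueError(
                f"n_processes must be in [0, {self.n_candidate_processes}], got {n}"
            )
        return self.baseline_term() - self.lambdas[:, :n] @ self.G[:, :n].T


def _orient_columns(G: np.ndarray, lam: np.ndarray) -> None:
    """Flip (G column, lambda column) pairs so each G column's largest-|.| entry is positive."""
    for a in range(G.shape[1]):
        j = int(np.argmax(np.abs(G[:, a])))
        if G[j, a] < 0:
            G[:, a] *= -1
            lam[:, a] *= -1


def _order_ties(S: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Stable descending order of S; exact ties broken by lexicographic G column."""
    order = np.argsort(-S, kind="stable")
    S_sorted = S[order]
    i = 0
    while i < len(order):
        j = i + 1
        while j < len(order) and S_sorted[j] == S_sorted[i]:
            j += 1
        if j - i > 1:
            tied = sorted(order[i:j], key=lambda c: tuple(V[:, c]))
            order[i:j] = tied
        i = j
    return order


def surprisal_decompose(matrix: ExpressionMatrix, max_rank: int | None = None) -> SADecomposition:
    """Factor the ln-expression matrix into baseline + unbalanced processes.

    Parameters
    ----------
    matrix
        Preprocessed expression matrix (no missing values). A log-scale
        matrix is factored verbatim; a linear-scale matrix is ln-transformed.
    max_rank
        Number of candidate processes to retain beyond the baseline
        (default: all, i.e. ``min(n_samples, n_analytes) - 1``). Retaining
        the full rank is recommended: the trailing components carry the
        noise estimate used for significance thresholds.
    """
    if matrix.missing_mask.any():
        raise ValueError("matrix has missing values; run preprocess first")
    M = matrix.log_values()
    n, m = M.shape
    full = min(n, m) - 1
    if max_rank is None:
        max_rank = full
    if not 1 <= max_rank <= full:
        raise ValueError(f"max_rank must be in [1, {full}], got {max_rank}")

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # baseline = dominant rank-one component, oriented to positive weights
    u0, s0, v0 = U[:, 0], S[0], Vt[0]
    if np.mean(u0) < 0:
        u0, v0 = -u0, -v0
    baseline_weights = s0 * u0
    baseline_pattern = v0.copy()

    S_proc, U_proc, V_proc = S[1:], U[:, 1:], Vt[1:].T
    avail = int(np.sum(S_proc > _RANK_TOL * max(S[0], 1.0)))
    if avail == 0:
        warnings.warn("matrix is (numerically) constant across samples: baseline only, zero processes")
    elif avail < max_rank:
        warnings.warn(f"rank deficient: only {avail} processes available (max_rank={max_rank})")
    r = min(max_rank, avail)

    order = _order_ties(S_proc[:r].copy(), V_proc[:, :r]) if r else np.array([], dtype=int)
    G = V_proc[:, order].copy()
    lambdas = -(U_proc[:, order] * S_proc[order])
    _orient_columns(G, lambdas)

    return SADecomposition(
        sample_ids=list(matrix.sample_ids),
        analyte_ids=list(matrix.analyte_ids),
        baseline_pattern=baseline_pattern,
        baseline_weights=baseline_weights,
        G=G,
        lambdas=lambdas,
        singular_values=S_proc[order].copy(),
    )


def reconstruct(decomp: SADecomposition, n_processes: int | None = None) -> ExpressionMatrix:
    """Log-scale expression matrix rebuilt from baseline + first ``n_processes``."""
    return ExpressionMatrix(
        list(decomp.sample_ids),
        list(decomp.analyte_ids),
        decomp.log_matrix(n_processes),
        scale="log",
    )


def process_signature_similarity(
    decomp_a: SADecomposition, alpha: int, decomp_b: SADecomposition, beta: int
) -> tuple[float, float]:
    """Pearson correlation of two process weight vectors over shared analytes.

    Returns ``(r, abs(r))``. The raw sign is reported but is not meaningful
    on its own: the orientation of each process is a convention, so two
    decompositions of related datasets may agree up to a global sign flip.
    Requires at least 3 shared analytes.
    """
    shared = [a for a in decomp_a.analyte_ids if a in set(decomp_b.analyte_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared analytes; need at least 3")
    ia = [decomp_a.analyte_ids.index(a) for a in shared]
    ib = [decomp_b.analyte_ids.index(a) for a in shared]
    r = float(stats.pearsonr(decomp_a.G[ia, alpha], decomp_b.G[ib, beta]).statistic)
    return r, abs(r)
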