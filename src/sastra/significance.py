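"""Significance calling: how many processes are real, which amplitudes exceed
error limits, and which proteins participate significantly in each process.

Two estimators are provided for the number of unbalanced processes:

``noise_floor``
    Keep adding processes while the next singular value stands clearly above
    the root-mean-square of the remaining (trailing) spectrum, which
    estimates the noise level. Deterministic and fast.
``permutation``
    Parallel analysis: singular values of column-wise permuted ln-matrices
    form a null spectrum; a process is retained while its singular value
    exceeds the chosen percentile of the null at the same index.

Amplitude thresholds ``T_a`` (error limits on lambda) come from either the
pooled standard deviation of the amplitudes of the non-retained (noise)
processes, or from an analyte bootstrap, times a multiplier (default 2.0,
i.e. roughly a two-sigma limit). Thresholds are per-process scalars, shared
by all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decompose import SADecomposition

__all__ = [
    "SignificanceModel",
    "estimate_num_processes",
    "estimate_lambda_thresholds",
    "significant_proteins",
    "fit_significance",
]


@dataclass
class SignificanceModel:
    """Retained process count, amplitude thresholds and significant-protein sets."""

    n_processes: int
    lambda_thresholds: np.ndarray  # per-process T_a >= 0
    g_thresholds: np.ndarray       # per-process threshold on |G_ia|
    significant_proteins: list[list[str]]  # per process, ordered by descending |G_ia|
    method_params: dict = field(default_factory=dict)


def _null_top_sv(R: np.ndarray, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Largest singular values of column-wise permuted copies of a residual matrix."""
    n = R.shape[0]
    out = np.empty(n_resamples)
    for b in range(n_resamples):
        perm = np.take_along_axis(
            R, rng.permuted(np.broadcast_to(np.arange(n)[:, None], R.shape), axis=0), axis=0
        )
        out[b] = np.linalg.svd(perm, compute_uv=False)[0]
    return out


def estimate_num_processes(
    decomp: SADecomposition,
    method: str = "noise_floor",
    n_resamples: int = 200,
    seed: int = 0,
    multiplier: float = 2.0,
    percentile: float = 95.0,
) -> int:
    """Number of unbalanced processes required to reproduce the data.

    See the module docstring for the two methods. Returns ``r``; ``r = 0``
    (data indistinguishable from noise) raises a warning, not an error.
    """
    S = decomp.singular_values
    if method == "noise_floor":
        # rank-deficient inputs drop sub-tolerance components; those ranks
        # still count as (exactly zero) trailing noise
        full = min(len(decomp.sample_ids), len(decomp.analyte_ids)) - 1
        S_full = np.concatenate([S, np.zeros(max(0, full - len(S)))])
        r = 0
        while r < len(S):
            noise = float(np.sqrt(np.mean(S_full[r:] ** 2)))
            if noise == 0.0:
                break
            if S[r] > multiplier * noise:
                r += 1
            else:
                break
    elif method == "permutation":
        if n_resamples < 20:
            raise ValueError("permutation method needs n_resamples >= 20")
        rng = np.random.default_rng(seed)
        # sequential parallel analysis: test process r+1 on the residual
        # after deflating baseline and the r accepted processes — permuting
        # the raw matrix instead would fold the accepted signal variance
        # into the null and mask weaker true processes
        r = 0
        while r < len(S):
            residual = decomp.lambdas[:, r:] @ decomp.G[:, r:].T
            cut = float(np.percentile(_null_top_sv(residual, n_resamples, rng), percentile))
            if S[r] > cut:
                r += 1
            else:
                break
    else:
        raise ValueError(f"unknown method {method!r}")
    if r == 0:
        warnings.warn("no process rises above the noise; data indistinguishable from noise")
    return r


def estimate_lambda_thresholds(
    decomp: SADecomposition,
    n_processes: int,
    method: str = "noise_edge",
    multiplier: float = 2.0,
    n_resamples: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Per-process amplitude error limits ``T_a`` (one scalar per process).

    ``noise_edge`` (recommended): ``T_a = multiplier * SD`` of the
    amplitudes of the *strongest* non-retained process. Pure noise produces
    amplitude patterns up to its spectral edge, so an amplitude is only
    distinguishable from noise if it exceeds what the largest noise
    component generates — the same logic by which parallel analysis compares
    each singular value to the top of the null spectrum.
    ``trailing_noise``: ``T_a = multiplier * SD`` of amplitudes pooled over
    *all* non-retained processes. This is the bulk noise floor of lambda
    space; it understates what extreme noise components reach, so it calls
    more false activations than ``noise_edge``.
    ``resample``: ``T_a = multiplier * SD`` of ``lambda_a`` under bootstrap
    resampling of analytes, per process.
    """
    if not 0 <= n_processes <= decomp.n_candidate_processes:
        raise ValueError("n_processes out of range")
    if method in ("trailing_noise", "noise_edge"):
        noise = decomp.lambdas[:, n_processes:]
        if noise.size == 0:
            warnings.warn("no trailing processes to estimate noise from; falling back to resample")
            return estimate_lambda_thresholds(
                decomp, n_processes, "resample", multiplier, n_resamples, seed
            )
        # trailing columns are ordered by singular value, so column 0 is the
        # strongest amplitude pattern noise alone produces
        sd = float(np.std(noise[:, 0])) if method == "noise_edge" else float(np.std(noise))
        return np.full(n_processes, multiplier * sd)
    if method == "resample":
        rng = np.random.default_rng(seed)
        m = len(decomp.analyte_ids)
        R = decomp.log_matrix() - decomp.baseline_term()  # -(lambda @ G.T) part
        G = decomp.G[:, :n_processes]
        boots = np.empty((n_resamples, len(decomp.sample_ids), n_processes))
        for b in range(n_resamples):
            idx = rng.integers(0, m, size=m)
            boots[b] = -(R[:, idx] @ G[idx])
        sd_per_sample = boots.std(axis=0)  # samples x processes
        return multiplier * np.sqrt(np.mean(sd_per_sample**2, axis=0))
    raise ValueError(f"unknown method {method!r}")


def significant_proteins(
    decomp: SADecomposition,
    n_processes: int,
    g_method: str = "quantile",
    g_param: float = 0.05,
) -> tuple[list[list[str]], np.ndarray]:
    """Per-process sets of significantly participating analytes.

    ``quantile``: the top ``g_param`` fraction of analytes by ``|G_ia|``
    (ties broken by analyte order). ``noise_sd``: analytes with ``|G_ia|``
    above ``g_param`` standard deviations of the loadings pooled over the
    non-retained (noise) processes. Returns the per-process lists ordered by
    descending ``|G_ia|`` plus the effective ``|G|`` threshold per process.
    """
    m = len(decomp.analyte_ids)
    sets: list[list[str]] = []
    thresholds = np.zeros(n_processes)
    if g_method == "quantile":
        if not 0 < g_param < 1:
            raise ValueError("quantile g_param must be in (0, 1)")
        k = max(1, int(np.ceil(g_param * m)))
    elif g_method == "noise_sd":
        noise_loadings = decomp.G[:, n_processes:]
        if noise_loadings.size == 0:
            raise ValueError("noise_sd method needs non-retained processes")
        sd = float(np.std(noise_loadings))
    else:
        raise ValueError(f"unknown g_method {g_method!r}")
    for a in range(n_processes):
        absg = np.abs(decomp.G[:, a])
        order = sorted(range(m), key=lambda i: (-absg[i], i))  # stable tie-break by analyte order
        if g_method == "quantile":
            chosen = order[:k]
            thresholds[a] = absg[order[k - 1]] if k <= m else 0.0
        else:
            thresholds[a] = g_param * sd
            chosen = [i for i in order if absg[i] > thresholds[a]]
        if not chosen:
            warnings.warn(f"process {a}: no significant proteins")
        sets.append([decomp.analyte_ids[i] for i in chosen])
    return sets, thresholds


def fit_significance(
    decomp: SADecomposition,
    num_method: str = "noise_floor",
    threshold_method: str = "noise_edge",
    g_method: str = "quantile",
    multiplier: float = 2.0,
    g_param: float = 0.05,
    n_resamples: int = 200,
    seed: int = 0,
    n_processes: int | None = None,
) -> SignificanceModel:
    """Run the full significance stage and record the settings used."""
    if n_processes is None:
        n_processes = estimate_num_processes(
            decomp, method=num_method, n_resamples=n_resamples, seed=seed, multiplier=multiplier
        )
    T = estimate_lambda_thresholds(
        decomp, n_processes, method=threshold_method,
        multiplier=multiplier, n_resamples=n_resamples, seed=seed,
    )
    sets, g_thr = significant_proteins(decomp, n_processes, g_method, g_param)
    return SignificanceModel(
        n_processes=n_processes,
        lambda_thresholds=T,
        g_thresholds=g_thr,
        significant_proteins=sets,
        method_params={
            "num_method": num_method,
            "threshold_method": threshold_method,
            "g_method": g_method,
            "multiplier": multiplier,
            "g_param": g_param,
            "n_resamples": n_resamples,
            "seed": seed,
        },
    )
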