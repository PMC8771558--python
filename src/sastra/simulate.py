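"""Synthetic cohorts with planted low-rank structure and known ground truth.

A cohort is built exactly the way the decomposition models real data: a
per-analyte steady-state log level shared by all samples, plus a handful of
sparse rank-one process terms, plus i.i.d. Gaussian noise on the log scale::

    ln X(k) = baseline + sum_a  G[:, a] * lambda_a(k) + noise

Each process touches ``support_size`` analytes, with 20% of the support
shared with the previous process by default (real hubs such as
phospho-receptors recur across processes). Per sample and process, the
amplitude is *active* with probability ``activation_prob`` — drawn, with a
random sign, from a band comfortably above the planted threshold — or
*inactive*, drawn from a band near zero. The noise SD is the mean active
amplitude divided by ``snr``. The planted ternary activation pattern is the
ground-truth barcode every pipeline stage is scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .barcode import pattern_string
from .decompose import SADecomposition
from .io import ExpressionMatrix, SampleMetadata
from .significance import SignificanceModel

__all__ = [
    "TreatmentEffect",
    "SyntheticGroundTruth",
    "generate_cohort",
    "RecoveryReport",
    "score_recovery",
]

# planted amplitude geometry, in units of the planted threshold
_ACTIVE_BAND = (2.0, 3.0)  # |lambda| of an active (sample, process)
# inactive amplitudes are exactly zero: a sample not engaged in a process
# deviates from the steady state only through noise, so the planted truth
# stays undetectable at any signal-to-noise ratio
# ratio between consecutive process amplitude scales: process 1 is the
# strongest, mirroring the decreasing abundance of real processes. Exactly
# degenerate process strengths would make the individual factors
# unidentifiable for any spectral method (the signal subspace is recovered
# but rotations within it are arbitrary), so the generator separates them —
# by enough that the spectrum stays separated even when a treatment effect
# silences one process in half of a paired cohort (a factor 1/sqrt(2) in
# pooled scale).
_STRENGTH_STEP = 2.0


@dataclass
class TreatmentEffect:
    """Planted effect applied to the paired after-treatment samples.

    ``abolish``: processes whose amplitudes are reset to the inactive band in
    every patient. ``induce``: process -> probability that a patient inactive
    on it before treatment becomes active after.
    """

    abolish: tuple[int, ...] = ()
    induce: dict[int, float] = field(default_factory=dict)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows: the planted model and its barcode."""

    baseline_log_levels: np.ndarray
    true_G: np.ndarray                 # analytes x processes, unit-norm sparse columns
    true_supports: list[list[int]]     # per process, the drawn analyte indices
    true_lambdas: np.ndarray           # samples x processes (before-treatment block)
    activation_pattern: np.ndarray     # samples x processes ternary (all rows of the matrix)
    lambda_threshold: float
    noise_sd: float
    snr: float
    seed: int
    metadata: SampleMetadata | None = None          # set for paired cohorts
    true_transitions: pd.DataFrame | None = None    # patient_id, process, class


def _strengths(n_processes: int) -> np.ndarray:
    """Per-process active-amplitude scale, strongest first; weakest is 1."""
    return _STRENGTH_STEP ** np.arange(n_processes - 1, -1, -1, dtype=float)


def _draw_amplitudes(rng, n_samples, n_processes, activation_prob, threshold):
    active = rng.random((n_samples, n_processes)) < activation_prob
    # signs are balanced among the active samples of each process: a process
    # deviates the cohort in both directions, and a net sign imbalance would
    # shift the process mean into the (unidentifiable) baseline term,
    # offsetting every inactive sample's estimated amplitude
    signs = np.zeros((n_samples, n_processes))
    for a in range(n_processes):
        n_act = int(active[:, a].sum())
        bal = np.repeat([-1.0, 1.0], [n_act // 2, n_act - n_act // 2])
        signs[active[:, a], a] = rng.permutation(bal)
    scale = _strengths(n_processes)[None, :]
    amp = rng.uniform(*_ACTIVE_BAND, size=(n_samples, n_processes)) * scale * threshold
    lam = signs * amp  # inactive entries are exactly zero
    pattern = np.sign(lam).astype(np.int8)
    return lam, pattern


def _orthogonalize_on_active(lam, active, n_sweeps=6):
    """Sequential Gram-Schmidt that spends its corrections on active entries only."""
    lam = lam.copy()
    r = lam.shape[1]
    for _ in range(n_sweeps):
        for j in range(r):
            mask = active[:, j]
            k = int(mask.sum())
            if k == 0:
                continue
            lam[mask, j] -= lam[:, j].sum() / k
            for i in range(r):
                if i == j:
                    continue
                denom = float(lam[mask, i] @ lam[mask, i])
                if denom < 1e-12:
                    continue
                lam[mask, j] -= (float(lam[:, j] @ lam[:, i]) / denom) * lam[mask, i]
    return lam


def _decorrelate_active(lam, active, threshold, max_iter=200, tol=1e-9):
    """Make amplitude columns mean-free and mutually orthogonal while keeping
    every entry inside its planted band (inactive entries stay exactly zero).

    The model's processes are independent constraints: finite-sample column
    means would leak into the baseline and cross-correlations would rotate
    any spectral factorization away from the planted factors. A plain
    orthogonalization can push active amplitudes below the threshold on
    small cohorts, so this alternates between (a) exact orthogonalization
    restricted to active entries and (b) re-clipping active amplitudes into
    a safe band above the threshold with their drawn sign, until both
    constraints hold.
    """
    lo = _ACTIVE_BAND[0] * 0.75 * threshold  # still comfortably above threshold
    hi_scale = _ACTIVE_BAND[1] * 1.25 * threshold
    strengths = _strengths(lam.shape[1])
    signs = np.sign(lam)
    for _ in range(max_iter):
        lam = _orthogonalize_on_active(lam, active, n_sweeps=2)
        clipped = lam.copy()
        for a in range(lam.shape[1]):
            mask = active[:, a]
            mag = np.clip(np.abs(lam[mask, a]), lo, hi_scale * strengths[a])
            clipped[mask, a] = signs[mask, a] * mag
            clipped[~mask, a] = 0.0
        moved = float(np.abs(clipped - lam).max())
        lam = clipped
        if moved < tol:
            break
    return lam


def generate_cohort(
    n_samples: int = 200,
    n_analytes: int = 150,
    n_processes: int = 3,
    support_size: int | None = None,
    support_overlap: float = 0.2,
    activation_prob: float = 0.3,
    snr: float = 10.0,
    lambda_threshold: float = 1.0,
    seed: int = 1,
    paired_treatment_effect: TreatmentEffect | None = None,
) -> tuple[ExpressionMatrix, SyntheticGroundTruth]:
    """Generate a log-scale expression matrix with planted process structure.

    With ``paired_treatment_effect``, each of the ``n_samples`` patients gets
    a before and an after sample (2 * n_samples rows, ids ``P###_before`` /
    ``P###_after``) whose pairing is recorded in the returned truth's
    ``metadata``; the planted per-patient transition classes are recorded in
    ``true_transitions``. Fully reproducible from ``seed``.
    """
    if not 1 <= n_processes <= 6:
        raise ValueError("n_processes must be in [1, 6]")
    if support_size is None:
        # 20 analytes per process at the default 150-analyte panel, shrunk
        # proportionally for smaller panels so supports stay feasible
        fresh_frac = 1 + (n_processes - 1) * (1 - support_overlap)
        support_size = min(20, max(2, int(n_analytes / (fresh_frac + 0.1))))
    if support_size > n_analytes:
        raise ValueError("support_size exceeds n_analytes")
    n_fresh = support_size + (n_processes - 1) * (
        support_size - int(round(support_overlap * support_size)))
    if n_fresh > n_analytes:
        raise ValueError(
            f"support_size {support_size} with overlap {support_overlap} needs "
            f"{n_fresh} analytes, only {n_analytes} available")
    if not 0 <= activation_prob < 1:
        raise ValueError("activation_prob must be in [0, 1)")
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for the noiseless limit)")
    rng = np.random.default_rng(seed)

    baseline = rng.normal(5.0, 1.0, size=n_analytes)

    # sparse supports: each process shares support_overlap of its analytes
    # with the previous process, the rest drawn from unused analytes
    n_ov = int(round(support_overlap * support_size))
    pool = list(rng.permutation(n_analytes))
    supports: list[list[int]] = []
    for a in range(n_processes):
        if a == 0 or n_ov == 0:
            sup = [pool.pop() for _ in range(support_size)]
        else:
            shared = list(rng.choice(supports[-1], size=n_ov, replace=False))
            sup = shared + [pool.pop() for _ in range(support_size - n_ov)]
        supports.append(sup)
    G = np.zeros((n_analytes, n_processes))
    for a, sup in enumerate(supports):
        # participating analytes carry weights bounded away from zero — a
        # negligible loading would mean the analyte does not participate
        w = rng.uniform(0.5, 1.5, size=len(sup)) * rng.choice([-1.0, 1.0], size=len(sup))
        G[sup, a] = w / np.linalg.norm(w)
    # the model's processes are deviations orthogonal to the steady-state
    # pattern and to each other; the non-orthogonal parts of a raw draw
    # would be absorbed by the baseline / rotated between processes and are
    # unrecoverable in principle, so plant exactly orthogonal columns
    # (Gram-Schmidt adds small off-support loadings, consistent with shared
    # hubs and a soft support boundary)
    b_hat = baseline / np.linalg.norm(baseline)
    for a in range(n_processes):
        G[:, a] -= b_hat * (b_hat @ G[:, a])
        G[:, a] -= G[:, :a] @ (G[:, :a].T @ G[:, a])
        G[:, a] /= np.linalg.norm(G[:, a])

    lam, pattern = _draw_amplitudes(rng, n_samples, n_processes, activation_prob, lambda_threshold)
    lam = _decorrelate_active(lam, pattern != 0, lambda_threshold)
    # SNR is defined against the *weakest* process (scale 1), the hardest to recover
    mean_active = lambda_threshold * np.mean(_ACTIVE_BAND)
    noise_sd = 0.0 if np.isinf(snr) else mean_active / snr

    def build_block(lam_block):
        noise = rng.normal(0.0, noise_sd, size=(lam_block.shape[0], n_analytes)) if noise_sd else 0.0
        return baseline[None, :] + lam_block @ G.T + noise

    if paired_treatment_effect is None:
        sample_ids = [f"S{k + 1:04d}" for k in range(n_samples)]
        matrix = ExpressionMatrix(sample_ids, [f"A{i + 1:03d}" for i in range(n_analytes)],
                                  build_block(lam), scale="log")
        truth = SyntheticGroundTruth(
            baseline_log_levels=baseline, true_G=G, true_supports=supports,
            true_lambdas=lam, activation_pattern=pattern,
            lambda_threshold=lambda_threshold, noise_sd=noise_sd, snr=snr, seed=seed,
        )
        return matrix, truth

    eff = paired_treatment_effect
    lam_after = lam.copy()
    for a in eff.abolish:
        lam_after[:, a] = 0.0
    strengths = _strengths(n_processes)
    for a, prob in eff.induce.items():
        inactive = pattern[:, a] == 0
        flip = np.nonzero(inactive & (rng.random(n_samples) < prob))[0]
        k = len(flip)
        bal = rng.permutation(np.repeat([-1.0, 1.0], [k // 2, k - k // 2]))
        lam_after[flip, a] = (
            bal * rng.uniform(*_ACTIVE_BAND, size=k) * strengths[a] * lambda_threshold
        )
    # the pooled factorization sees before and after samples as one cohort,
    # so decorrelate the stacked amplitude matrix (signs and activity are
    # preserved, as in the unpaired case)
    lam_all = _decorrelate_active(
        np.vstack([lam, lam_after]), np.vstack([lam, lam_after]) != 0, lambda_threshold)
    lam, lam_after = lam_all[:n_samples], lam_all[n_samples:]
    pattern = np.sign(lam).astype(np.int8)
    pattern_after = np.sign(lam_after).astype(np.int8)

    ids_before = [f"P{k + 1:03d}_before" for k in range(n_samples)]
    ids_after = [f"P{k + 1:03d}_after" for k in range(n_samples)]
    analyte_ids = [f"A{i + 1:03d}" for i in range(n_analytes)]
    matrix = ExpressionMatrix(
        ids_before + ids_after, analyte_ids, build_block(lam_all), scale="log"
    )
    meta = SampleMetadata(pd.DataFrame({
        "cancer_type": ["synthetic"] * (2 * n_samples),
        "timepoint": ["before"] * n_samples + ["after"] * n_samples,
        "patient_id": [f"P{k + 1:03d}" for k in range(n_samples)] * 2,
    }, index=ids_before + ids_after))
    from .treatment import classify_transition
    trans = pd.DataFrame([
        {"patient_id": f"P{k + 1:03d}", "process": a + 1,
         "class": classify_transition(int(pattern[k, a]), int(pattern_after[k, a]))}
        for k in range(n_samples) for a in range(n_processes)
    ])
    truth = SyntheticGroundTruth(
        baseline_log_levels=baseline, true_G=G, true_supports=supports,
        true_lambdas=lam, activation_pattern=np.vstack([pattern, pattern_after]),
        lambda_threshold=lambda_threshold, noise_sd=noise_sd, snr=snr, seed=seed,
        metadata=meta, true_transitions=trans,
    )
    return matrix, truth


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted structure."""

    n_processes_true: int
    n_processes_est: int
    matching: list[tuple[int, int, float]]  # (true idx, est idx, signed G correlation)
    mean_abs_correlation: float
    sensitivity: float
    specificity: float
    ari: float


def score_recovery(
    truth: SyntheticGroundTruth,
    decomp: SADecomposition,
    sig: SignificanceModel,
    barcodes: pd.DataFrame,
) -> RecoveryReport:
    """Score estimated processes/barcodes/subgroups against the planted truth.

    Estimated processes are matched one-to-one to planted ones by maximal
    ``|corr(G_est, G_true)|`` (Hungarian assignment). Process orientation is
    a convention, so each matched estimate is sign-aligned to the truth by
    the sign of that correlation times the model's minus sign before
    barcodes are compared. Sensitivity counts truly active (sample, process)
    entries recovered with the correct sign; specificity counts truly
    inactive entries called inactive. Subgroup agreement is the adjusted
    Rand index between the partitions induced by estimated and true
    barcodes.
    """
    n_true = truth.true_G.shape[1]
    n_est = sig.n_processes
    pattern = truth.activation_pattern
    est_codes = barcodes.to_numpy()

    matching: list[tuple[int, int, float]] = []
    aligned = np.zeros_like(pattern, dtype=np.int8)
    if n_est > 0:
        C = np.array([
            [float(np.corrcoef(truth.true_G[:, t], decomp.G[:, e])[0, 1]) for e in range(n_est)]
            for t in range(n_true)
        ])
        rows, cols = linear_sum_assignment(-np.abs(C))
        for t, e in zip(rows, cols):
            matching.append((int(t), int(e), float(C[t, e])))
            # model is ln X = baseline - G lambda; the generator plants
            # +G lambda, so a positive G correlation implies lambda_est ~ -lambda_true
            s = -int(np.sign(C[t, e])) or 1
            aligned[:, t] = s * est_codes[:, e]
    mean_abs_r = float(np.mean([abs(r) for _, _, r in matching])) if matching else 0.0

    active = pattern != 0
    sens = float(np.mean(aligned[active] == pattern[active])) if active.any() else 1.0
    spec = float(np.mean(aligned[~active] == 0)) if (~active).any() else 1.0

    true_labels = [pattern_string(row) for row in pattern]
    est_labels = [pattern_string(row) for row in est_codes]
    ari = float(adjusted_rand_score(true_labels, est_labels))

    return RecoveryReport(
        n_processes_true=n_true,
        n_processes_est=n_est,
        matching=matching,
        mean_abs_correlation=mean_abs_r,
        sensitivity=sens,
        specificity=spec,
        ari=ari,
    )
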