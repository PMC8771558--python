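"""Per-sample drug-combination planning from active unbalanced processes.

The working hypothesis: every active process sustains part of the altered
signaling flux, so at least one central hub protein from *every* active
process must be targeted for the flux to collapse; inhibiting one process
leaves the others to drive resistance. Hubs are nominated by participation
weight ``|G_ia|`` among the process's significant proteins, preferring
proteins that are upregulated in the given sample (inhibitors act on
induced activity) and that map to a known drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decompose import SADecomposition
from .io import TargetDrugMap
from .significance import SignificanceModel

__all__ = [
    "ProcessTarget",
    "TargetPlan",
    "recommend_combination",
    "combination_probability",
    "joint_selection_bound",
]


@dataclass
class ProcessTarget:
    """Chosen hub target for one active process in one sample."""

    process: int                 # 0-based process index
    barcode_state: int           # -1 or +1
    candidates: list[tuple[str, float, int]]  # (analyte, |G|, direction in this sample)
    chosen: str | None
    drugs: list[str]
    flags: list[str] = field(default_factory=list)


@dataclass
class TargetPlan:
    """Ranked hub targets per active process and the pooled drug combination."""

    sample_id: str
    process_targets: list[ProcessTarget]

    @property
    def drugs(self) -> list[str]:
        """Deduplicated union of drugs, in process order."""
        seen: dict[str, None] = {}
        for pt in self.process_targets:
            for d in pt.drugs:
                seen.setdefault(d)
        return list(seen)

    @property
    def covered_processes(self) -> set[int]:
        return {pt.process for pt in self.process_targets if pt.chosen is not None}

    @property
    def active_processes(self) -> set[int]:
        return {pt.process for pt in self.process_targets}


def recommend_combination(
    barcode_entries: np.ndarray,
    sample_id: str,
    decomp: SADecomposition,
    sig: SignificanceModel,
    drug_map: TargetDrugMap,
    druggable_only: bool = True,
    max_targets_per_process: int = 1,
) -> TargetPlan:
    """Assemble the drug combination covering every active process of one sample.

    For each process with a nonzero barcode entry, significant proteins are
    ranked by ``|G_ia|`` (ties by analyte order). The direction of change of
    analyte ``i`` in this sample is ``sign(-G_ia * lambda_a(k))`` — the minus
    sign of the model equation. The chosen target is the top-ranked protein
    that is upregulated in the sample and (if ``druggable_only``) present in
    the drug map; if none qualifies, the top protein overall is chosen and
    the process flagged. Drugs shared across processes are deduplicated.
    ``max_targets_per_process > 1`` nominates additional hubs for highly
    active processes.
    """
    entries = np.asarray(barcode_entries)
    if entries.shape[0] != sig.n_processes:
        raise ValueError("barcode length does not match number of retained processes")
    k = decomp.sample_ids.index(sample_id)
    plan: list[ProcessTarget] = []
    for a in np.nonzero(entries)[0]:
        lam = decomp.lambdas[k, a]
        cands = []
        for analyte in sig.significant_proteins[a]:
            i = decomp.analyte_ids.index(analyte)
            g = decomp.G[i, a]
            direction = int(np.sign(-g * lam))
            cands.append((analyte, abs(g), direction))
        flags: list[str] = []
        chosen_list: list[str] = []
        if not cands:
            flags.append("no_candidates")
        else:
            preferred = [c for c in cands if c[2] > 0 and (not druggable_only or c[0] in drug_map)]
            if preferred:
                chosen_list = [c[0] for c in preferred[:max_targets_per_process]]
            else:
                chosen_list = [cands[0][0]]
                flags.append("no_druggable_upregulated")
        drugs: list[str] = []
        for t in chosen_list:
            drugs.extend(drug_map.drugs_for(t))
        if chosen_list and not drugs:
            flags.append("unmapped_target")
        plan.append(ProcessTarget(
            process=int(a),
            barcode_state=int(entries[a]),
            candidates=cands,
            chosen=chosen_list[0] if chosen_list else None,
            drugs=list(dict.fromkeys(drugs)),
            flags=flags,
        ))
    if not plan:
        warnings.warn(f"sample {sample_id!r}: barcode has no active process; empty plan")
    return TargetPlan(sample_id=sample_id, process_targets=plan)


def combination_probability(process_counts, cohort_size: int) -> float:
    """Upper bound on the probability of drawing a given set of processes at random.

    Each process's marginal probability is its prevalence ``count / cohort``;
    the bound is the product of the marginals (independent-draw upper bound).
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    p = 1.0
    for c in process_counts:
        if not 0 <= c <= cohort_size:
            raise ValueError(f"count {c} outside [0, {cohort_size}]")
        p *= c / cohort_size
    return p


def joint_selection_bound(counts_a, counts_b, cohort_size: int) -> float:
    """Joint bound for two independent selections (e.g. a 2-process and a
    3-process signature): the product of the two set probabilities."""
    return combination_probability(counts_a, cohort_size) * combination_probability(
        counts_b, cohort_size
    )
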