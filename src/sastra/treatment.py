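"""Pre/post-treatment barcode comparison.

Before- and after-treatment samples must be barcoded against the *same*
decomposition (a joint factorization of the pooled matrix) so that process
indices mean the same thing at both timepoints. Each (patient, process)
transition is then classified from the pair of ternary states:

===============  ==========================
before -> after  class
===============  ==========================
x != 0 -> 0      abolished
0 -> x != 0      induced
x -> x (x != 0)  persistent
x -> -x (x != 0) sign_flipped
0 -> 0           inactive
===============  ==========================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import SADecomposition
from .io import SampleMetadata
from .significance import SignificanceModel

__all__ = ["classify_transition", "ProcessTransitionTable", "compare_pre_post", "analyte_direction_change"]


def classify_transition(before: int, after: int) -> str:
    """Pure classification of one (state_before, state_after) pair."""
    if before not in (-1, 0, 1) or after not in (-1, 0, 1):
        raise ValueError("states must be ternary")
    if before == 0 and after == 0:
        return "inactive"
    if before != 0 and after == 0:
        return "abolished"
    if before == 0 and after != 0:
        return "induced"
    return "persistent" if before == after else "sign_flipped"


@dataclass
class ProcessTransitionTable:
    """Per-patient, per-process transition classes plus cohort summary counts."""

    table: pd.DataFrame   # patient_id, process, state_before, state_after, class [, marker flag]
    summary: pd.DataFrame  # class -> count (split by marker participation if annotated)

    def counts(self) -> pd.Series:
        return self.table["class"].value_counts()


def compare_pre_post(
    barcodes_before: pd.DataFrame,
    barcodes_after: pd.DataFrame,
    pairing: SampleMetadata,
    sig: SignificanceModel | None = None,
    annotate_analyte: str | None = None,
) -> ProcessTransitionTable:
    """Classify every paired patient's processes as abolished/induced/....

    ``pairing`` supplies (patient_id, before sample, after sample) triples via
    its timepoint/patient_id columns; samples without a complete pair are
    excluded with a warning. When ``annotate_analyte`` is given (e.g. a
    receptor of interest) together with ``sig``, each row records whether
    that analyte participates significantly in the process, and the summary
    is split by that flag.
    """
    if barcodes_before.shape[1] != barcodes_after.shape[1]:
        raise ValueError("before/after barcodes have different numbers of processes")
    n_proc = barcodes_before.shape[1]
    marker_procs: set[int] = set()
    if annotate_analyte is not None:
        if sig is None:
            raise ValueError("annotate_analyte requires the SignificanceModel")
        marker_procs = {
            a for a in range(sig.n_processes)
            if annotate_analyte in sig.significant_proteins[a]
        }
    rows = []
    for patient, s_before, s_after in pairing.pairs():
        if s_before not in barcodes_before.index or s_after not in barcodes_after.index:
            warnings.warn(f"patient {patient!r}: missing barcode for one timepoint; excluded")
            continue
        b = barcodes_before.loc[s_before].to_numpy()
        a = barcodes_after.loc[s_after].to_numpy()
        for proc in range(n_proc):
            rec = {
                "patient_id": patient,
                "process": proc + 1,
                "state_before": int(b[proc]),
                "state_after": int(a[proc]),
                "class": classify_transition(int(b[proc]), int(a[proc])),
            }
            if annotate_analyte is not None:
                rec["marker_in_process"] = proc in marker_procs
            rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        summary = pd.DataFrame(columns=["class", "count"])
    elif annotate_analyte is not None:
        summary = (
            table.groupby(["marker_in_process", "class"]).size().rename("count").reset_index()
        )
    else:
        summary = table.groupby("class").size().rename("count").reset_index()
    return ProcessTransitionTable(table=table, summary=summary)


def analyte_direction_change(
    decomp: SADecomposition, analyte: str, process: int, sample_before: str, sample_after: str
) -> int:
    """Sign of the change in one analyte's contribution from process ``process``
    between two samples: ``sign(-G_ia * (lambda_after - lambda_before))``.

    Annotates statements like "the receptor's level increased due to the
    induced process"; it is a readout of the fitted model, not a new fit.
    """
    i = decomp.analyte_ids.index(analyte)
    kb = decomp.sample_ids.index(sample_before)
    ka = decomp.sample_ids.index(sample_after)
    delta = decomp.lambdas[ka, process] - decomp.lambdas[kb, process]
    return int(np.sign(-decomp.G[i, process] * delta))
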