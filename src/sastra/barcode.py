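"""Ternary signaling barcodes and cohort stratification.

A sample's barcode has one entry per retained process: ``+1`` if the
amplitude significantly exceeds its error limit with positive sign, ``-1``
with negative sign, ``0`` otherwise (amplitudes exactly at the limit are
insignificant — "exceed" is strict). Samples with element-wise identical
barcodes form a subgroup: they carry the same set of altered processes and
are hypothesised to respond to the same drug combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import SADecomposition
from .io import ExpressionMatrix, SampleMetadata
from .significance import SignificanceModel

__all__ = [
    "make_barcode",
    "barcode_frame",
    "pattern_string",
    "SubgroupTable",
    "stratify",
    "summarize_process_usage",
    "marker_prevalence",
    "MarkerPrevalence",
]

_CHARS = {-1: "-", 0: "0", 1: "+"}


def make_barcode(lambdas_row: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Ternary-code one amplitude vector against the per-process error limits."""
    lam = np.asarray(lambdas_row, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    if lam.shape != thr.shape:
        raise ValueError(f"length mismatch: {lam.shape} amplitudes vs {thr.shape} thresholds")
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite amplitude")
    return np.where(np.abs(lam) > thr, np.sign(lam), 0).astype(np.int8)


def barcode_frame(decomp: SADecomposition, sig: SignificanceModel) -> pd.DataFrame:
    """Barcodes for every sample: DataFrame samples x process_1..process_n."""
    n = sig.n_processes
    codes = np.vstack([
        make_barcode(decomp.lambdas[k, :n], sig.lambda_thresholds)
        for k in range(len(decomp.sample_ids))
    ]) if n else np.zeros((len(decomp.sample_ids), 0), dtype=np.int8)
    cols = [f"process_{a + 1}" for a in range(n)]
    return pd.DataFrame(codes, index=list(decomp.sample_ids), columns=cols, dtype=np.int8)


def pattern_string(entries) -> str:
    """Serialise a ternary barcode as a string over {-, 0, +}."""
    return "".join(_CHARS[int(e)] for e in entries)


@dataclass
class SubgroupTable:
    """Barcode-identical subgroups, largest first.

    ``table`` columns: subgroup (1-based rank), pattern, size, members
    (semicolon-joined sample ids) and, when metadata is given, composition
    columns counting members per cancer type / anatomical region.
    ``per_stratum`` counts unique barcodes within each metadata stratum.
    """

    table: pd.DataFrame
    per_stratum: pd.DataFrame | None = None

    @property
    def n_subgroups(self) -> int:
        return len(self.table)


def stratify(barcodes: pd.DataFrame, metadata: SampleMetadata | None = None) -> SubgroupTable:
    """Group samples with element-wise identical barcodes into subgroups.

    Subgroups are ordered by descending size, ties by lexicographic pattern
    string. With metadata, per-subgroup composition by cancer type and
    region, and per-stratum unique-barcode counts, are included.
    """
    if barcodes.shape[1] and barcodes.apply(lambda c: c.isin([-1, 0, 1]).all()).sum() != barcodes.shape[1]:
        raise ValueError("barcodes must be ternary (-1/0/+1)")
    groups: dict[str, list[str]] = {}
    for sid, row in zip(barcodes.index, barcodes.to_numpy()):
        groups.setdefault(pattern_string(row), []).append(str(sid))
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for rank, (pat, members) in enumerate(ordered, start=1):
        rec = {"subgroup": rank, "pattern": pat, "size": len(members),
               "members": ";".join(members)}
        if metadata is not None:
            md = metadata.table
            known = [m for m in members if m in md.index]
            for col in ("cancer_type", "anatomical_region"):
                counts = md.loc[known, col].dropna().value_counts()
                rec[col] = ";".join(f"{v}:{c}" for v, c in counts.items())
        rows.append(rec)
    table = pd.DataFrame(rows)
    per_stratum = None
    if metadata is not None:
        md = metadata.table
        pat_by_sample = {str(s): pattern_string(r) for s, r in zip(barcodes.index, barcodes.to_numpy())}
        strata = []
        for col in ("cancer_type", "anatomical_region"):
            series = md[col].dropna()
            for value, grp in series.groupby(series):
                ids = [s for s in grp.index.astype(str) if s in pat_by_sample]
                if ids:
                    strata.append({
                        "stratum": col, "value": value, "n_samples": len(ids),
                        "n_unique_barcodes": len({pat_by_sample[s] for s in ids}),
                    })
        per_stratum = pd.DataFrame(strata)
    return SubgroupTable(table, per_stratum)


def summarize_process_usage(
    barcodes: pd.DataFrame, expected_range: tuple[int, int] = (2, 4)
) -> dict[str, pd.Series]:
    """Per-process nonzero counts and per-sample active-process counts.

    ``flagged`` lists samples whose number of active processes falls outside
    ``expected_range`` (a diagnostic — most tumors carry a handful of
    altered processes, not zero and not all of them).
    """
    if barcodes.empty:
        return {
            "per_process": pd.Series(dtype=int),
            "per_sample": pd.Series(dtype=int),
            "flagged": pd.Series(dtype=int),
        }
    nz = barcodes != 0
    per_process = nz.sum(axis=0)
    per_sample = nz.sum(axis=1)
    lo, hi = expected_range
    return {
        "per_process": per_process,
        "per_sample": per_sample,
        "flagged": per_sample[(per_sample < lo) | (per_sample > hi)],
    }


@dataclass
class MarkerPrevalence:
    analyte: str
    median: float               # over the FULL dataset, linear scale
    n_cohort: int
    n_at_or_below_median: int
    n_below_fold_median: int
    fold: float

    @property
    def frac_at_or_below_median(self) -> float:
        return self.n_at_or_below_median / self.n_cohort

    @property
    def frac_below_fold_median(self) -> float:
        return self.n_below_fold_median / self.n_cohort


def marker_prevalence(
    matrix: ExpressionMatrix,
    analyte: str,
    cohort_filter=None,
    fold: float = 1.5,
) -> MarkerPrevalence:
    """How many cohort samples express a marker at/below the dataset median.

    The median is computed over the *full* dataset on the linear scale
    (log input is exponentiated); counts are over the filtered cohort:
    samples at or below the median (ties count), and samples strictly below
    ``fold`` times the median.
    """
    if analyte not in matrix.analyte_ids:
        raise KeyError(f"analyte {analyte!r} not in matrix")
    j = matrix.analyte_ids.index(analyte)
    col = matrix.linear_values()[:, j]
    med = float(np.median(col))
    if cohort_filter is None:
        sel = np.ones(len(col), dtype=bool)
    else:
        wanted = set(map(str, cohort_filter))
        sel = np.array([s in wanted for s in matrix.sample_ids])
    sub = col[sel]
    return MarkerPrevalence(
        analyte=analyte,
        median=med,
        n_cohort=int(sel.sum()),
        n_at_or_below_median=int((sub <= med).sum()),
        n_below_fold_median=int((sub < fold * med).sum()),
        fold=fold,
    )
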