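"""Reading, validation and preprocessing of expression tables and annotation tables.

Expression tables are delimited text (TSV/CSV) with one header row of analyte
ids and one leading column of sample ids (TCPA-style), or the transpose.
A matrix is either on a *linear* scale (raw expression, must be positive
after preprocessing) or a *log* scale (taken verbatim as natural-log
expression; TCPA level-4 RPPA tables are already log-like normalised and may
contain negative values, so no further transform is applied to them).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens in a cell that mark a missing measurement
_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "TargetDrugMap",
    "PreprocessReport",
    "read_expression_table",
    "write_expression_table",
    "preprocess",
    "read_metadata",
    "read_target_map",
    "example_drug_map",
]


@dataclass
class ExpressionMatrix:
    """Samples x analytes expression values with scale metadata.

    Parameters
    ----------
    sample_ids, analyte_ids
        Unique ordered identifiers for rows and columns of ``values``.
    values
        Dense float matrix, rows = samples, columns = analytes.
    scale
        ``"linear"`` (positive expression units) or ``"log"`` (natural-log
        expression, dimensionless; may be negative).
    missing_mask
        Boolean matrix, True where the measurement is absent. Values under
        the mask are NaN until :func:`preprocess` imputes them.
    """

    sample_ids: list[str]
    analyte_ids: list[str]
    values: np.ndarray
    scale: str = "log"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.analyte_ids = [str(a) for a in self.analyte_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise ValueError("duplicate analyte ids")
        if self.values.shape != (len(self.sample_ids), len(self.analyte_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analyte_ids)} analytes"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def log_values(self) -> np.ndarray:
        """Values on the natural-log scale (identity for scale='log')."""
        if self.scale == "log":
            return self.values
        if np.any(self.values[~self.missing_mask] <= 0):
            raise ValueError("linear-scale matrix contains non-positive values; run preprocess first")
        return np.log(self.values)

    def linear_values(self) -> np.ndarray:
        """Values on the linear scale (exponentiates log input)."""
        return np.exp(self.values) if self.scale == "log" else self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.analyte_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(sample_ids), list(self.analyte_ids),
            self.values[idx], self.scale, self.missing_mask[idx],
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: cancer type, anatomical region, treatment timepoint."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("cancer_type",)
    OPTIONAL = ("anatomical_region", "timepoint", "patient_id")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in self.table.columns:
                self.table[col] = pd.NA
        bad_tp = set(self.table["timepoint"].dropna()) - {"before", "after"}
        if bad_tp:
            raise ValueError(f"timepoint values must be 'before'/'after', got {sorted(bad_tp)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def cancer_type(self, sample_id: str) -> str:
        return self.table.loc[sample_id, "cancer_type"]

    def pairs(self) -> list[tuple[str, str, str]]:
        """(patient_id, before_sample, after_sample) for complete pairs."""
        tp = self.table.dropna(subset=["timepoint", "patient_id"])
        out = []
        for pid, grp in tp.groupby("patient_id", sort=True):
            by_tp = dict(zip(grp["timepoint"], grp.index))
            if "before" in by_tp and "after" in by_tp:
                out.append((str(pid), str(by_tp["before"]), str(by_tp["after"])))
            else:
                warnings.warn(f"patient {pid!r} lacks a complete before/after pair; excluded")
        return out


@dataclass
class TargetDrugMap:
    """Mapping from analyte ids (or target aliases) to drug names."""

    table: pd.DataFrame  # columns: target, drug, optional notes

    def __post_init__(self) -> None:
        for col in ("target", "drug"):
            if col not in self.table.columns:
                raise ValueError(f"target map missing required column {col!r}")
        # alias -> canonical id must be unambiguous (case-insensitive match)
        lowered = self.table["target"].str.lower()
        canon = self.table.groupby(lowered)["target"].nunique()
        if (canon > 1).any():
            bad = canon[canon > 1].index.tolist()
            raise ValueError(f"aliases resolving to multiple targets: {bad}")
        self._by_target = {
            key: list(dict.fromkeys(grp["drug"]))
            for key, grp in self.table.groupby(lowered, sort=False)
        }

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id.lower() in self._by_target

    def drugs_for(self, analyte_id: str) -> list[str]:
        return list(self._by_target.get(analyte_id.lower(), []))


@dataclass
class PreprocessReport:
    dropped_analytes: list[str] = field(default_factory=list)
    n_imputed: int = 0
    shift: float = 0.0


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    return df


def read_expression_table(
    path: str | Path,
    scale: str = "log",
    orientation: str = "samples_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Blank cells (or NA tokens) become missing values; any other non-numeric
    cell is a hard error naming its row and column. ``orientation`` says which
    axis of the *file* carries samples; the in-memory matrix is always
    samples x analytes.
    """
    if orientation not in ("samples_in_rows", "analytes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "analytes_in_rows":
        df = df.T
    values = np.empty(df.shape, dtype=float)
    mask = np.zeros(df.shape, dtype=bool)
    for j, col in enumerate(df.columns):
        for i, (row, cell) in enumerate(zip(df.index, df[col])):
            cell = cell.strip()
            if cell.lower() in _NA_TOKENS:
                values[i, j] = np.nan
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at sample {row!r}, analyte {col!r}"
                    ) from None
    return ExpressionMatrix(list(df.index), list(df.columns), values, scale, mask)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path, digits: int = 6) -> None:
    """Write a matrix as TSV (samples in rows), missing cells blank."""
    df = matrix.to_frame().copy()
    df[pd.DataFrame(matrix.missing_mask, index=df.index, columns=df.columns)] = np.nan
    df.to_csv(path, sep="\t", float_format=f"%.{digits}g", na_rep="")


def preprocess(
    matrix: ExpressionMatrix,
    max_missing_frac: float = 0.3,
    pseudocount: float = 1e-6,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Drop gappy analytes, median-impute the rest, and enforce positivity.

    Analytes missing in more than ``max_missing_frac`` of samples are removed;
    remaining gaps are filled with the analyte's median across samples. On a
    linear-scale matrix, if any value is <= 0 the whole matrix is shifted by
    ``pseudocount - min`` so every value is positive (order-preserving).
    Idempotent: a second application is a no-op.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    report = PreprocessReport()
    frac = matrix.missing_mask.mean(axis=0)
    keep = frac <= max_missing_frac
    report.dropped_analytes = [a for a, k in zip(matrix.analyte_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all analytes exceed the missing-data threshold")
    values = matrix.values[:, keep].copy()
    mask = matrix.missing_mask[:, keep]
    analyte_ids = [a for a, k in zip(matrix.analyte_ids, keep) if k]
    if mask.any():
        med = np.nanmedian(np.where(mask, np.nan, values), axis=0)
        ii, jj = np.nonzero(mask)
        values[ii, jj] = med[jj]
        report.n_imputed = int(mask.sum())
    if matrix.scale == "linear":
        lo = values.min()
        if lo <= 0:
            report.shift = pseudocount - lo
            values = values + report.shift
    if report.dropped_analytes or report.n_imputed or report.shift:
        logger.info(
            "preprocess: dropped %d analytes, imputed %d cells, shift %+g",
            len(report.dropped_analytes), report.n_imputed, report.shift,
        )
    out = ExpressionMatrix(
        list(matrix.sample_ids), analyte_ids, values, matrix.scale,
        np.zeros_like(values, dtype=bool),
    )
    return out, report


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(Path(path), sep=None, engine="python", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_target_map(path: str | Path) -> TargetDrugMap:
    df = pd.read_csv(Path(path), sep=None, engine="python", dtype=str)
    return TargetDrugMap(df)


def example_drug_map() -> TargetDrugMap:
    """The bundled target->drug table of commonly used targeted inhibitors."""
    from importlib.resources import files

    path = files("sastra").joinpath("data/drug_map.tsv")
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    return TargetDrugMap(df)
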