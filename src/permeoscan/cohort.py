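"""Cohort data model and I/O.

The analysis operates on a gene-by-sample expression matrix (non-negative
values in FPKM-UQ, TPM, counts or arbitrary units), a per-sample clinical
table (right-censored survival time, event indicator, covariates) and named
gene sets.  This module defines those containers, enforces their invariants,
and reads/writes them as tab-delimited text (expression: genes as rows,
header row of sample identifiers; clinical: one row per sample; gene sets:
one identifier per line, or GMT).

Cohorts from tumor repositories often carry several sequenced samples per
patient; when a patient-identifier depth is given, only the
lexicographically first sample per patient is retained so each patient
contributes one observation to survival models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("FPKM-UQ", "TPM", "counts", "arbitrary")
VALID_ENDPOINTS = ("OS", "PFS")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSet",
    "CohortError",
    "ParseError",
    "InputError",
    "load_cohort",
    "load_expression",
    "load_clinical",
    "load_gene_sets",
    "write_cohort",
]


class CohortError(Exception):
    """Base class for cohort data errors."""


class ParseError(CohortError):
    """A file cell could not be interpreted (non-numeric or negative value)."""


class InputError(CohortError):
    """Inputs violate a cohort-level invariant (duplicates, empty sets, ...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Non-negative gene-by-sample expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  All entries must be finite and >= 0.
    unit
        One of ``FPKM-UQ``, ``TPM``, ``counts`` or ``arbitrary``.
    """

    values: pd.DataFrame
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise InputError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite expression value at gene {self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative expression value {arr[g, s]!r} at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], unit=self.unit)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids), :], unit=self.unit)

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and covariates.

    ``data`` is indexed by sample identifier and carries ``time`` (days, > 0),
    ``event`` (1 = event observed, 0 = right-censored) and any number of
    covariate columns (numeric, or binary-encoded categorical).  Missing
    covariate values are permitted; models restrict to complete cases.
    """

    data: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise InputError(f"unknown endpoint {self.endpoint!r}; expected one of {VALID_ENDPOINTS}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise InputError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers in clinical table: {dups[:5]}")
        time = self.data["time"].to_numpy(dtype=float)
        if not (np.isfinite(time).all() and (time > 0).all()):
            bad = self.data.index[~(np.isfinite(time) & (time > 0))][0]
            raise InputError(f"non-positive or non-finite survival time for sample {bad!r}")
        event = self.data["event"].to_numpy()
        if not np.isin(event, (0, 1)).all():
            bad = self.data.index[~np.isin(event, (0, 1))][0]
            raise InputError(f"event indicator not in {{0,1}} for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)], endpoint=self.endpoint)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def present_in(self, matrix: ExpressionMatrix) -> list[str]:
        """Members present in ``matrix``, in matrix row order."""
        return [g for g in matrix.gene_ids if g in self.members]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    *,
    unit: str = "arbitrary",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (genes as rows by default)."""
    numeric = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if transpose:
        numeric = numeric.T
    non_numeric = [c for c in numeric.columns if not np.issubdtype(numeric[c].dtype, np.number)]
    if non_numeric or numeric.isna().to_numpy().any():
        # re-read as text to name the offending cell
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if transpose:
            raw = raw.T
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna().to_numpy()
        g, s = np.argwhere(bad)[0]
        value = raw.iloc[g, s]
        kind = "missing" if pd.isna(value) else f"non-numeric ({value!r})"
        raise ParseError(
            f"{kind} expression value at gene {raw.index[g]!r}, sample {raw.columns[s]!r} in {path}"
        )
    return ExpressionMatrix(numeric.astype(float), unit=unit)


def load_clinical(path: str | Path, *, endpoint: str = "OS") -> ClinicalTable:
    """Read a tab-delimited clinical table with sample_id, time, event columns."""
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "sample_id" not in raw.columns:
        raise InputError(f"clinical table {path} lacks a sample_id column")
    raw = raw.set_index("sample_id")
    return ClinicalTable(raw, endpoint=endpoint)


def _first_sample_per_patient(
    sample_ids: Iterable[str], delimiter: str, depth: int | None
) -> list[str]:
    """Keep the lexicographically first sample identifier per patient.

    The patient identifier is the sample identifier truncated to ``depth``
    delimiter-separated fields; ``depth=None`` means no collapsing.
    """
    if depth is None:
        return sorted(sample_ids)
    kept: dict[str, str] = {}
    for sid in sorted(sample_ids):
        patient = delimiter.join(sid.split(delimiter)[:depth])
        kept.setdefault(patient, sid)
    return list(kept.values())


def load_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    *,
    unit: str = "arbitrary",
    endpoint: str = "OS",
    transpose: bool = False,
    patient_delimiter: str = "-",
    patient_depth: int | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Load and align an expression matrix with its clinical table.

    The pair is restricted to the intersection of sample identifiers,
    preserving the expression matrix's sample order.  When ``patient_depth``
    is given, sample identifiers are collapsed to patients (first
    ``patient_depth`` ``patient_delimiter``-separated fields) and only the
    lexicographically first sample per patient is retained.
    """
    matrix = load_expression(expression_path, unit=unit, transpose=transpose)
    clinical = load_clinical(clinical_path, endpoint=endpoint)
    clinical_ids = set(
        _first_sample_per_patient(clinical.sample_ids, patient_delimiter, patient_depth)
    )
    shared = [s for s in matrix.sample_ids if s in clinical_ids]
    if not shared:
        raise InputError("no samples shared between expression matrix and clinical table")
    return matrix.subset_samples(shared), clinical.subset_samples(shared)


def write_cohort(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable | None,
    expression_path: str | Path,
    clinical_path: str | Path | None = None,
) -> None:
    """Write a cohort as TSV at full float precision (round-trip safe)."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(expression_path, sep="\t", float_format="%.17g")
    if clinical is not None:
        if clinical_path is None:
            raise InputError("clinical_path required when writing a clinical table")
        cdat = clinical.data.copy()
        cdat.index.name = "sample_id"
        cdat.to_csv(clinical_path, sep="\t", float_format="%.17g")


def _parse_gene_set_lines(path: Path) -> list[tuple[str, list[str]]]:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if any(ln.count("\t") >= 2 for ln in lines) or path.suffix.lower() == ".gmt":
        sets = []
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed GMT line in {path}: {ln!r}")
            sets.append((fields[0], [g for g in fields[2:] if g]))
        return sets
    return [(path.stem, [ln.strip() for ln in lines])]


def load_gene_sets(paths: Sequence[str | Path]) -> dict[str, GeneSet]:
    """Read gene sets from plain-text (one id per line) or GMT files.

    Duplicated identifiers are removed with a warning stating how many were
    dropped.  An empty set after deduplication is an error.
    """
    out: dict[str, GeneSet] = {}
    for path in paths:
        path = Path(path)
        for name, members in _parse_gene_set_lines(path):
            unique = list(dict.fromkeys(members))
            n_dup = len(members) - len(unique)
            if n_dup:
                warnings.warn(
                    f"gene set {name!r}: removed {n_dup} duplicate identifier(s)",
                    stacklevel=2,
                )
            if not unique:
                raise InputError(f"gene set {name!r} in {path} is empty")
            if name in out:
                raise InputError(f"duplicate gene set name {name!r}")
            out[name] = GeneSet(name=name, members=frozenset(unique))
    return out
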