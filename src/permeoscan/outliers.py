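"""Highly elevated ("outlier") and switch-like gene expression.

A sample has outlier expression of a gene when its value exceeds the gene's
75th percentile across the cohort by 1.5 times the interquartile range
(Tukey's rule), computed per gene within one cohort.  The per-gene
fold-change is the ratio of median expression in the outlier samples to
median expression in the non-outlier samples.  A gene is *switch-like* when
its cohort median is exactly zero while more than zero but fewer than half
of the samples express it; such genes are annotated separately, since their
non-outlier median is zero and the fold-change is undefined.

Quantiles use linear interpolation between order statistics (the scientific
computing default); the comparison with the threshold is strict, so ties at
the cut are not outliers.  Both conventions are configurable where they
matter.  Only elevation is called — there is no low-tail rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, GeneSet, InputError

__all__ = [
    "OutlierProfile",
    "tukey_outlier_calls",
    "classify_switch_like",
    "gene_outlier_summary",
    "sample_outlier_burden",
    "profile_frame",
]

TUKEY_K = 1.5  # IQR multiplier of the outlier rule


@dataclass
class OutlierProfile:
    """Per-gene outlier and switch-like annotation within one cohort."""

    gene_id: str
    threshold: float
    outlier_mask: np.ndarray
    outlier_fraction: float
    fold_change: float            # NaN when undefined (non-outlier median 0 or no outliers)
    switch_like: bool
    nonzero_fraction: float
    median_nonzero: float         # NaN when the gene is never expressed


def tukey_outlier_calls(
    values: np.ndarray, *, k: float = TUKEY_K, quantile_method: str = "linear"
) -> tuple[float, np.ndarray]:
    """Tukey upper-fence outlier calls on one gene's cohort values.

    Returns ``(threshold, mask)`` with ``threshold = Q75 + k * (Q75 - Q25)``
    and ``mask[i]`` true iff ``values[i] > threshold`` (strict).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 4:
        raise InputError("Tukey outlier calls need a 1-D vector of length >= 4")
    if not np.isfinite(values).all() or (values < 0).any():
        raise InputError("values must be finite and non-negative")
    q25, q75 = np.quantile(values, (0.25, 0.75), method=quantile_method)
    threshold = q75 + k * (q75 - q25)
    return float(threshold), values > threshold


def classify_switch_like(values: np.ndarray) -> tuple[bool, float, float]:
    """Switch-like classification: cohort median zero, 0 < non-zero fraction < 1/2.

    Returns ``(switch_like, nonzero_fraction, median_nonzero)``;
    ``median_nonzero`` is NaN when no sample expresses the gene.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InputError("switch-like classification needs a 1-D vector of length >= 2")
    nonzero = values > 0
    nonzero_fraction = float(nonzero.mean())
    median_nonzero = float(np.median(values[nonzero])) if nonzero.any() else float("nan")
    switch = bool(np.median(values) == 0 and 0 < nonzero_fraction < 0.5)
    return switch, nonzero_fraction, median_nonzero


def _present_members(matrix: ExpressionMatrix, genes: GeneSet) -> list[str]:
    present = genes.present_in(matrix)
    if not present:
        raise InputError(f"no member of gene set {genes.name!r} is present in the matrix")
    n_absent = len(genes) - len(present)
    if n_absent:
        warnings.warn(
            f"gene set {genes.name!r}: {n_absent} member(s) absent from the matrix were dropped",
            stacklevel=3,
        )
    return present


def gene_outlier_summary(
    matrix: ExpressionMatrix, genes: GeneSet, *, k: float = TUKEY_K
) -> list[OutlierProfile]:
    """Outlier/switch-like profile for every set member present in the matrix.

    Fold-change is the ratio of outlier-group to non-outlier-group median
    expression, NaN when either group is empty or the denominator is zero
    (such genes are excluded from fold-change summaries rather than
    pseudocounted; zero-median genes are covered by the switch-like flag).
    """
    profiles = []
    for gene in _present_members(matrix, genes):
        row = matrix.gene_values(gene)
        threshold, mask = tukey_outlier_calls(row, k=k)
        fold = float("nan")
        if mask.any() and (~mask).any():
            denom = float(np.median(row[~mask]))
            if denom > 0:
                fold = float(np.median(row[mask]) / denom)
        switch, nz_frac, med_nz = classify_switch_like(row)
        profiles.append(
            OutlierProfile(
                gene_id=gene,
                threshold=threshold,
                outlier_mask=mask,
                outlier_fraction=float(mask.mean()),
                fold_change=fold,
                switch_like=switch,
                nonzero_fraction=nz_frac,
                median_nonzero=med_nz,
            )
        )
    return profiles


def sample_outlier_burden(
    matrix: ExpressionMatrix, genes: GeneSet, *, k: float = TUKEY_K
) -> pd.Series:
    """Per-sample fraction of the gene set's present members called outlier."""
    profiles = gene_outlier_summary(matrix, genes, k=k)
    masks = np.vstack([p.outlier_mask for p in profiles])
    return pd.Series(masks.mean(axis=0), index=matrix.sample_ids, name="outlier_burden")


def profile_frame(profiles: list[OutlierProfile]) -> pd.DataFrame:
    """Tabular view of profiles (one row per gene; masks omitted)."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "threshold": [p.threshold for p in profiles],
            "outlier_fraction": [p.outlier_fraction for p in profiles],
            "fold_change": [p.fold_change for p in profiles],
            "switch_like": [p.switch_like for p in profiles],
            "nonzero_fraction": [p.nonzero_fraction for p in profiles],
            "median_nonzero": [p.median_nonzero for p in profiles],
        }
    ).set_index("gene_id")
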