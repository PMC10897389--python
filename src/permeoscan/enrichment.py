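"""Permutation test for excess outlier expression of a gene set.

Whether a target gene set (e.g., the ion permeome) is more strongly and
more frequently upregulated than expectation is judged against control gene
sets down-sampled *with replacement* to the target's size: each iteration
draws |target| control genes and records the median fold-change (over genes
with a defined fold-change) and the median outlier-sample fraction.  The
empirical p-value counts null draws whose median meets or exceeds the
observed one, with add-one smoothing:

    p = (#{null >= observed} + 1) / (n_iterations + 1)

so the attainable floor is 1/(n_iterations+1) and results at the floor are
flagged.  A *representative iteration* — the draw whose null median
fold-change is the lower median of the null vector — is reported so a
typical control draw can be plotted next to the observed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ExpressionMatrix, GeneSet, InputError
from .outliers import gene_outlier_summary

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    """Observed vs resampled-control outlier statistics for one gene set."""

    observed_median_fc: float        # NaN when no target gene has a defined FC
    observed_median_fraction: float
    null_median_fc: np.ndarray       # one entry per iteration (NaN possible)
    null_median_fraction: np.ndarray
    p_fc: float                      # NaN when the FC statistic is unavailable
    p_fraction: float
    representative_iteration: int
    n_iterations: int
    n_drawn: int
    seed: int

    @property
    def fc_test_available(self) -> bool:
        return np.isfinite(self.observed_median_fc)

    def at_floor(self) -> dict[str, bool]:
        """Which p-values sit at the smoothed Monte-Carlo floor 1/(n+1)."""
        floor = 1.0 / (self.n_iterations + 1)
        return {
            "p_fc": bool(np.isfinite(self.p_fc) and self.p_fc <= floor),
            "p_fraction": bool(self.p_fraction <= floor),
        }


def _smoothed_p(null: np.ndarray, observed: float) -> float:
    exceed = np.nansum(null >= observed)  # NaN comparisons are False
    return float((exceed + 1) / (null.size + 1))


def _lower_median_index(values: np.ndarray) -> int:
    """Index of the lower-median finite entry (first iteration on ties)."""
    finite = np.flatnonzero(np.isfinite(values))
    if finite.size == 0:
        return 0
    order = finite[np.argsort(values[finite], kind="stable")]
    return int(order[(finite.size - 1) // 2])


def permutation_test(
    matrix: ExpressionMatrix,
    target: GeneSet,
    control: GeneSet,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical significance of a gene set's outlier magnitude and frequency.

    The two observed statistics are the medians over target genes of the
    per-gene fold-change (genes with undefined fold-change dropped) and of
    the per-gene outlier-sample fraction.  Null statistics come from
    ``n_iterations`` draws of |target-present| control genes with
    replacement, with the same undefined-FC handling per draw.
    Deterministic given ``seed``.
    """
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    target_profiles = gene_outlier_summary(matrix, target)
    control_profiles = gene_outlier_summary(matrix, control)

    t_fc = np.array([p.fold_change for p in target_profiles])
    t_frac = np.array([p.outlier_fraction for p in target_profiles])
    c_fc = np.array([p.fold_change for p in control_profiles])
    c_frac = np.array([p.outlier_fraction for p in control_profiles])

    with np.errstate(all="ignore"):
        observed_fc = float(np.nanmedian(t_fc)) if np.isfinite(t_fc).any() else float("nan")
    observed_frac = float(np.median(t_frac))

    k = t_fc.size
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, c_fc.size, size=(n_iterations, k))
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN draws are legitimate
            null_fc = np.nanmedian(c_fc[draws], axis=1)
    null_frac = np.median(c_frac[draws], axis=1)

    p_fc = _smoothed_p(null_fc, observed_fc) if np.isfinite(observed_fc) else float("nan")
    p_frac = _smoothed_p(null_frac, observed_frac)

    return PermutationResult(
        observed_median_fc=observed_fc,
        observed_median_fraction=observed_frac,
        null_median_fc=null_fc,
        null_median_fraction=null_frac,
        p_fc=p_fc,
        p_fraction=p_frac,
        representative_iteration=_lower_median_index(null_fc),
        n_iterations=n_iterations,
        n_drawn=k,
        seed=seed,
    )
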