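"""Risk grouping, group survival comparison, feature association, rank maps.

Cohorts are dichotomized by a gene's expression — at the median (ties at
the median go to the low group) or by the Tukey outlier call (high group =
outlier samples) — or by a binary molecular feature (mutation present,
promoter methylation high, copy-number gain/loss).  Group survival is
compared with a Cox proportional-hazards fit on the group indicator
(optionally adjusted for covariates such as patient age) and summarized by
Kaplan–Meier curves emitted as data tables.

Expression–feature association uses the two-sided Mann–Whitney U test per
gene with Benjamini–Hochberg FDR control within the analysis.  Rank
normalization maps each sample's expression profile to fractional ranks in
[0, 1] (average ranks on ties), allowing a gene's standing to be compared
across datasets measured in different units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ClinicalTable, ExpressionMatrix, InputError
from .outliers import tukey_outlier_calls
from .prioritize import FitError

__all__ = [
    "RiskGrouping",
    "GroupSurvivalResult",
    "GroupingError",
    "dichotomize",
    "group_survival_test",
    "feature_association",
    "rank_normalize",
]

EXACT_MWU_MAX_N = 20  # exact U distribution below this per-group size, no ties


class GroupingError(Exception):
    """The requested dichotomization produces an empty group."""


@dataclass
class RiskGrouping:
    """A two-group split of samples by a gene or binary feature."""

    name: str
    method: str                       # median | tukey_outlier | binary_feature
    labels: pd.Series                 # per-sample group label
    high_label: str = "high"
    low_label: str = "low"

    @property
    def n_high(self) -> int:
        return int((self.labels == self.high_label).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == self.low_label).sum())

    def indicator(self) -> pd.Series:
        """1 for the high/present group, 0 otherwise."""
        return (self.labels == self.high_label).astype(int)


@dataclass
class GroupSurvivalResult:
    """Cox comparison of two risk groups plus Kaplan–Meier curves."""

    hr: float
    ci95: tuple[float, float]
    wald_p: float
    km_curves: dict[str, pd.DataFrame]  # label -> columns: time, survival, at_risk
    warnings: list[str] = field(default_factory=list)


def dichotomize(
    values: np.ndarray | pd.Series,
    method: str,
    *,
    name: str = "feature",
    sample_ids=None,
) -> RiskGrouping:
    """Split samples into high/low (or present/absent) groups.

    ``median``: high iff value strictly above the median (ties at the median
    go low).  ``tukey_outlier``: high iff the Tukey outlier call is true.
    ``binary_feature``: values must be 0/1; present iff 1.  An empty
    resulting group raises :class:`GroupingError` — the caller reports the
    feature as untestable.
    """
    if isinstance(values, pd.Series):
        sample_ids = values.index if sample_ids is None else sample_ids
        values = values.to_numpy()
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = pd.RangeIndex(values.size)
    high_label, low_label = "high", "low"
    if method == "median":
        high = values > np.median(values)
    elif method == "tukey_outlier":
        _, high = tukey_outlier_calls(values)
    elif method == "binary_feature":
        if not np.isin(values, (0, 1)).all():
            raise InputError("binary_feature dichotomization requires 0/1 values")
        high = values == 1
        high_label, low_label = "present", "absent"
    else:
        raise InputError(f"unknown dichotomization method {method!r}")
    if high.all() or not high.any():
        raise GroupingError(
            f"{method} dichotomization of {name!r} leaves an empty group"
        )
    labels = pd.Series(np.where(high, high_label, low_label), index=sample_ids, name=name)
    return RiskGrouping(
        name=name, method=method, labels=labels,
        high_label=high_label, low_label=low_label,
    )


def _km_table(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    surv = km.survival_function_
    at_risk = km.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def group_survival_test(
    grouping: RiskGrouping,
    clinical: ClinicalTable,
    covariate_names: tuple[str, ...] = (),
) -> GroupSurvivalResult:
    """Cox PH comparison of the two risk groups with Kaplan–Meier curves.

    The hazard ratio is for the high (present) group versus the low
    (absent) group, optionally adjusted for clinical covariates.  A group
    without events yields an "HR unstable" warning but the fit is still
    attempted; complete separation raises :class:`FitError`.
    """
    shared = [s for s in clinical.sample_ids if s in grouping.labels.index]
    if not shared:
        raise InputError("no samples shared between grouping and clinical table")
    indicator = grouping.indicator().loc[shared]
    clin = clinical.subset_samples(shared)
    if indicator.nunique() < 2:
        raise GroupingError("both risk groups must be non-empty")
    if clin.event.sum() < 2:
        raise InputError("group survival test needs at least 2 events")

    notes = []
    for label in (grouping.high_label, grouping.low_label):
        in_group = grouping.labels.loc[shared] == label
        if clin.event[in_group.to_numpy()].sum() == 0:
            notes.append(f"no events in group {label!r}; hazard ratio unstable")

    df = pd.DataFrame({"group": indicator.to_numpy(dtype=float)}, index=shared)
    for c in covariate_names:
        df[c] = clin.data[c].to_numpy(dtype=float)
    df["time"], df["event"] = clin.time, clin.event
    df = df.dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"group Cox fit failed (possible complete separation): {exc}") from exc
    log_hr = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    curves = {}
    for label in (grouping.high_label, grouping.low_label):
        in_group = (grouping.labels.loc[shared] == label).to_numpy()
        curves[label] = _km_table(clin.time[in_group], clin.event[in_group])
    return GroupSurvivalResult(
        hr=float(np.exp(log_hr)),
        ci95=(float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))),
        wald_p=float(cph.summary.loc["group", "p"]),
        km_curves=curves,
        warnings=notes,
    )


def _mwu_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact for small tie-free groups, else normal
    approximation with tie correction."""
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def feature_association(
    matrix: ExpressionMatrix,
    gene_ids: list[str],
    feature_groups: pd.Series,
    analysis_name: str = "association",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene expression difference between two sample groups.

    ``feature_groups`` is a boolean/0-1 Series indexed by sample identifier
    (True = feature present).  Multi-class features should be supplied as
    one-vs-rest binaries by the caller.  Returns one row per gene with
    ``log2_fc`` (log2 ratio of group median expression, present over
    absent; NaN on zero denominator), the two-sided Mann–Whitney ``u_p``,
    the Benjamini–Hochberg ``fdr`` computed within this analysis, and a
    significance flag at ``fdr < fdr_threshold``.
    """
    samples = [s for s in matrix.sample_ids if s in feature_groups.index]
    groups = feature_groups.loc[samples].astype(bool).to_numpy()
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise InputError("both feature groups need at least 2 samples")
    missing = [g for g in gene_ids if g not in matrix.values.index]
    if missing:
        raise InputError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[gene_ids, samples].to_numpy(dtype=float)
    rows = []
    for gid, row in zip(gene_ids, sub):
        a, b = row[groups], row[~groups]
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_b > 0:
            with np.errstate(divide="ignore"):
                log2_fc = float(np.log2(med_a / med_b)) if med_a > 0 else float("-inf")
        else:
            log2_fc = float("nan")
        rows.append({"gene_id": gid, "log2_fc": log2_fc, "u_p": _mwu_two_sided(a, b)})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["fdr"] = multipletests(out["u_p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["analysis_name"] = analysis_name
    return out


def rank_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Within-sample fractional gene ranks scaled to [0, 1].

    Average ranks on ties; the lowest-expressed gene of a sample maps to 0
    and the highest to 1, so a gene's rank is comparable between cohorts
    measured in different units.
    """
    if matrix.n_genes < 2:
        raise InputError("rank normalization needs at least 2 genes")
    ranks = stats.rankdata(matrix.values.to_numpy(dtype=float), axis=0, method="average")
    scaled = (ranks - 1.0) / (matrix.n_genes - 1.0)
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns),
        unit="arbitrary",
    )
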