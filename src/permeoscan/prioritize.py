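"""Survival-gene prioritization by elastic-net Cox stability selection.

The procedure repeatedly fits penalized Cox proportional-hazards models on
random subsamples and keeps genes that are retained often:

1. draw a random subset of 80% of samples (without replacement);
2. pre-select genes associated with survival on the subsample in univariate
   Cox regression (Wald p < 0.1);
3. fit an elastic-net Cox model (L1-ratio 0.5) on the pre-selected genes
   plus all clinical covariates, choosing the penalty strength by 5-fold
   cross-validated concordance on the subsample;
4. record the features with non-zero coefficients.

After B iterations (default 1000) the selection frequency of each feature
is the fraction of completed iterations that recorded it; features with
frequency strictly above 50% are selected, and their effect sizes are
reported as univariate hazard ratios with 95% confidence intervals and Wald
p-values on the full cohort.  Calibration re-runs the whole procedure on
cohorts whose survival outcomes have been shuffled against the fixed
expression profiles; a well-calibrated run selects far fewer genes on
shuffled outcomes.

Gene features are standardized log1p expression; standardization is done
within each subsample before penalized fitting because elastic-net
penalties are scale-sensitive.  Covariates bypass pre-selection, are always
offered to the penalized model and are penalized like genes.  Efron tie
handling is used throughout (ties are certain with day-resolution survival
times).

Implementation notes: the single stand-alone fits (``univariate_coxph``,
``multivariate_vetting``) go through lifelines' ``CoxPHFitter``; the
per-iteration univariate screening and the full-cohort per-feature hazard
table use a vectorized single-coefficient Newton solver (Efron partial
likelihood) that fits all genes at once, since the procedure performs on
the order of B × p univariate fits.  The two routes are cross-checked in
the test suite.  The penalized path is scikit-survival's coordinate-descent
elastic net.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cohort import ClinicalTable, ExpressionMatrix, GeneSet, InputError

__all__ = [
    "PrioritizationConfig",
    "SelectionResult",
    "CalibrationResult",
    "FitError",
    "ProcedureError",
    "filter_expressed",
    "univariate_coxph",
    "cox_univariate_batch",
    "stability_selection",
    "shuffled_label_calibration",
    "multivariate_vetting",
    "apply_selection_threshold",
]


class FitError(Exception):
    """A survival model could not be fitted on the given data."""


class ProcedureError(Exception):
    """The resampling procedure failed (too many broken iterations)."""


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationConfig:
    """Stability-selection settings.

    Defaults follow the reference workflow: B = 1000 subsamples of 80% of
    samples, univariate Wald pre-selection at p < 0.1, elastic net with
    L1-ratio 0.5 and a 5-fold cross-validated penalty, selection at a strict
    >50% recurrence threshold, and a detectable-expression filter at mean
    expression > 1 in the matrix's native unit.
    """

    n_iterations: int = 1000
    subsample_fraction: float = 0.8
    preselect_alpha: float = 0.1
    preselect_on_full_cohort: bool = False
    l1_ratio: float = 0.5
    penalty_grid: Sequence[float] | str = "auto"
    n_penalties: int = 30
    penalty_min_ratio: float = 0.001
    cv_folds: int = 5
    penalty_rule: str = "1se"  # "1se" | "max"
    selection_threshold: float = 0.5
    min_mean_expression: float = 1.0
    covariate_names: Sequence[str] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction < 1:
            raise InputError("subsample_fraction must be in (0, 1)")
        if not 0 <= self.l1_ratio <= 1:
            raise InputError("l1_ratio must be in [0, 1]")
        if not 0 < self.selection_threshold < 1:
            raise InputError("selection_threshold must be in (0, 1)")
        if self.n_iterations < 1 or self.cv_folds < 2:
            raise InputError("n_iterations >= 1 and cv_folds >= 2 required")


@dataclass
class SelectionResult:
    """Per-feature selection frequencies and univariate effect sizes.

    ``table`` is indexed by feature name with columns ``kind`` (gene or
    covariate), ``selection_frequency``, ``selected``, ``log_hr``, ``hr``,
    ``hr_ci_low``, ``hr_ci_high`` and ``wald_p`` (univariate, full cohort).
    """

    table: pd.DataFrame
    n_iterations_completed: int
    n_iterations_failed: int
    config: PrioritizationConfig

    def selected_genes(self) -> list[str]:
        t = self.table
        return list(t.index[(t["kind"] == "gene") & t["selected"]])

    def selected_covariates(self) -> list[str]:
        t = self.table
        return list(t.index[(t["kind"] == "covariate") & t["selected"]])


@dataclass
class CalibrationResult:
    """Observed stability selection next to shuffled-outcome re-runs."""

    observed: SelectionResult
    shuffled: list[SelectionResult]
    table: pd.DataFrame  # one row per run: run, n_selected_genes, n_selected_covariates

    def shuffled_gene_counts(self) -> np.ndarray:
        return self.table.loc[self.table["run"] != "observed", "n_selected_genes"].to_numpy()


# ---------------------------------------------------------------------------
# expression filter and feature transform
# ---------------------------------------------------------------------------

def filter_expressed(matrix: ExpressionMatrix, min_mean: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose arithmetic mean expression strictly exceeds ``min_mean``."""
    means = matrix.values.mean(axis=1)
    keep = matrix.values.index[means > min_mean]
    if len(keep) == 0:
        raise InputError(f"no gene has mean expression > {min_mean}")
    return matrix.subset_genes(list(keep))


def log1p_features(matrix: ExpressionMatrix, gene_ids: Sequence[str]) -> np.ndarray:
    """Samples-by-genes log1p expression (model feature orientation)."""
    return np.log1p(matrix.values.loc[list(gene_ids)].to_numpy(dtype=float).T)


# ---------------------------------------------------------------------------
# univariate Cox — lifelines front-end and vectorized batch solver
# ---------------------------------------------------------------------------

def univariate_coxph(
    feature: np.ndarray, clinical: ClinicalTable
) -> tuple[float, float, tuple[float, float], float]:
    """Single-feature Cox PH fit (Efron ties) via lifelines.

    Returns ``(log_hr, hr, (ci_low, ci_high), wald_p)`` with the 95% CI from
    the normal approximation ``exp(log_hr ± 1.96 · SE)``.  Complete-case:
    samples with a missing feature value are dropped.
    """
    feature = np.asarray(feature, dtype=float)
    keep = np.isfinite(feature)
    feature, time, event = feature[keep], clinical.time[keep], clinical.event[keep]
    if event.sum() < 2:
        raise FitError("univariate Cox fit needs at least 2 events")
    if np.std(feature) == 0:
        raise FitError("feature has zero variance among complete cases")
    df = pd.DataFrame({"x": feature, "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:  # pragma: no cover - degenerate inputs
        raise FitError(f"Cox fit did not converge: {exc}") from exc
    log_hr = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    ci = (float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se)))
    return log_hr, float(np.exp(log_hr)), ci, float(cph.summary.loc["x", "p"])


def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    *,
    max_iter: int = 25,
    tol: float = 1e-9,
    beta_cap: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one univariate Cox model per column of ``X`` simultaneously.

    Newton–Raphson on the Efron partial likelihood, vectorized over
    features.  Returns ``(beta, se, wald_p)`` arrays of length ``p``.
    Coefficients are capped at ``±beta_cap`` (monotone-likelihood guard for
    separated features); such features report large effects with wide
    standard errors rather than failing.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape

    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]

    # unique event times, their first index in the ascending sort, and the
    # rows of X that die at each
    event_idx = np.flatnonzero(event == 1)
    if event_idx.size < 2:
        raise FitError("batch Cox fit needs at least 2 events")
    death_times = time[event_idx]
    uniq_times, first_of = np.unique(death_times, return_index=True)
    groups = [event_idx[first_of[i]: (first_of[i + 1] if i + 1 < uniq_times.size else event_idx.size)]
              for i in range(uniq_times.size)]
    # risk-set start: first sorted index with time >= t
    risk_start = np.searchsorted(time, uniq_times, side="left")

    beta = np.zeros(p)
    from scipy import stats as _stats

    for _ in range(max_iter):
        eta = X * beta  # (n, p)
        eta -= eta.max(axis=0)  # stabilize exp; cancels in all ratios
        w = np.exp(eta)
        wx = w * X
        wxx = wx * X
        cw = np.cumsum(w[::-1], axis=0)[::-1]
        cwx = np.cumsum(wx[::-1], axis=0)[::-1]
        cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]

        U = np.zeros(p)
        I = np.zeros(p)
        for g, start in zip(groups, risk_start):
            d = g.size
            S_r, Sx_r, Sxx_r = cw[start], cwx[start], cwxx[start]
            S_d = w[g].sum(axis=0)
            Sx_d = wx[g].sum(axis=0)
            Sxx_d = wxx[g].sum(axis=0)
            U += X[g].sum(axis=0)
            for l in range(d):
                f = l / d
                denom = S_r - f * S_d
                num1 = Sx_r - f * Sx_d
                num2 = Sxx_r - f * Sxx_d
                U -= num1 / denom
                I += num2 / denom - (num1 / denom) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 0, U / np.maximum(I, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -beta_cap, beta_cap)
        if np.max(np.abs(step)) < tol:
            break

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(I > 0, 1.0 / np.sqrt(np.maximum(I, 1e-300)), np.inf)
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    pvals = 2.0 * _stats.norm.sf(np.abs(z))
    return beta, se, pvals


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

def apply_selection_threshold(frequencies: pd.Series, threshold: float) -> pd.Series:
    """Selected iff frequency strictly exceeds the threshold (ties excluded)."""
    return frequencies > threshold


def _covariate_matrix(clinical: ClinicalTable, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in clinical.data.columns]
    if missing:
        raise InputError(f"covariates absent from clinical table: {missing}")
    return clinical.data[list(names)].to_numpy(dtype=float)


def _iteration_rng(seed: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))


def _cindex_path(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> np.ndarray:
    """Harrell's concordance for every column of a risk-score path at once.

    Comparable pairs are (i, j) with ``t_i < t_j`` and ``e_i = 1``, or tied
    times where exactly sample i had the event; tied risk scores count 0.5
    (same convention as sksurv's ``concordance_index_censored``).  Returns
    NaN when no pair is comparable.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    comparable = ((t_i < t_j) | ((t_i == t_j) & (event[None, :] == 0))) & (event[:, None] == 1)
    np.fill_diagonal(comparable, False)
    ii, jj = np.nonzero(comparable)
    if ii.size == 0:
        return np.full(risk.shape[1], np.nan)
    diff = risk[ii] - risk[jj]  # (n_pairs, n_alphas)
    concordant = (diff > 0).sum(axis=0) + 0.5 * (diff == 0).sum(axis=0)
    return concordant / ii.size


def _cv_choose_alpha(
    genes_raw: np.ndarray,
    covs_raw: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    config: "PrioritizationConfig",
    rng: np.random.Generator,
    fixed_pre_mask: np.ndarray | None = None,
) -> int:
    """Index of the cross-validated penalty, with nested pre-selection.

    Each fold repeats the univariate Wald pre-selection on its training
    part only, fits the penalty path there, and scores held-out
    concordance; the pre-selection is never allowed to see the test fold.
    Running it once on the whole subsample and cross-validating afterwards
    inflates held-out concordance (the features were picked partly for
    their correlation with the test fold's outcomes — the classic
    gene-selection bias), which drags the chosen penalty toward zero and
    lets every chance correlate through.  When pre-selection is configured
    on the full cohort (``fixed_pre_mask``), that mask is used unchanged.

    ``config.penalty_rule="max"`` takes the penalty maximizing mean CV
    concordance; ``"1se"`` (default) takes the largest penalty within one
    standard error of that maximum — the usual parsimony rule for penalty
    paths, without which the near-flat concordance curve past the signal
    knee drifts the choice toward weak penalties.
    """
    n = genes_raw.shape[0]
    cv_folds = config.cv_folds
    fold_of = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(fold_of)
    scores = np.full((cv_folds, alphas.size), np.nan)
    for fold in range(cv_folds):
        test = fold_of == fold
        train = ~test
        if event[train].sum() < 2 or event[test].sum() < 1:
            continue
        Xtr_g, Xte_g = genes_raw[train], genes_raw[test]
        mu, sd = Xtr_g.mean(axis=0), Xtr_g.std(axis=0)
        ok = sd > 0
        if fixed_pre_mask is not None:
            pre = fixed_pre_mask & ok
        else:
            pre = np.zeros(genes_raw.shape[1], dtype=bool)
            if ok.any():
                Ztr = (Xtr_g[:, ok] - mu[ok]) / sd[ok]
                try:
                    _, _, p_tr = cox_univariate_batch(Ztr, time[train], event[train])
                except FitError:
                    continue
                pre[ok] = p_tr < config.preselect_alpha
        blocks_tr, blocks_te = [], []
        if pre.any():
            blocks_tr.append((Xtr_g[:, pre] - mu[pre]) / sd[pre])
            blocks_te.append((Xte_g[:, pre] - mu[pre]) / sd[pre])
        if covs_raw.size:
            Ctr, Cte = covs_raw[train], covs_raw[test]
            cmu, csd = Ctr.mean(axis=0), Ctr.std(axis=0)
            c_ok = csd > 0
            if c_ok.any():
                blocks_tr.append((Ctr[:, c_ok] - cmu[c_ok]) / csd[c_ok])
                blocks_te.append((Cte[:, c_ok] - cmu[c_ok]) / csd[c_ok])
        if not blocks_tr:
            scores[fold] = 0.5  # empty model at every penalty
            continue
        Xtr = np.hstack(blocks_tr)
        Xte = np.hstack(blocks_te)
        est = CoxnetSurvivalAnalysis(
            l1_ratio=config.l1_ratio, alphas=alphas, fit_baseline_model=False
        )
        try:
            est.fit(Xtr, Surv.from_arrays(event[train].astype(bool), time[train]))
        except (ArithmeticError, ValueError):
            continue
        risk = Xte @ _coef_path(est, alphas)  # (n_test, n_alphas)
        scores[fold] = _cindex_path(time[test], event[test], risk)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_scores = np.nanmean(scores, axis=0)
    if not np.isfinite(mean_scores).any():
        raise FitError("cross-validation produced no finite concordance score")
    best = np.nanmax(mean_scores)
    # alphas are ordered large -> small; the first index at/above the cut is
    # the largest (sparsest) admissible penalty
    best_j = int(np.flatnonzero(mean_scores == best)[0])
    if config.penalty_rule == "max":
        return best_j
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_folds_used = np.sum(np.isfinite(scores[:, best_j]))
        se = np.nanstd(scores[:, best_j], ddof=1) / np.sqrt(max(n_folds_used, 1))
    if not np.isfinite(se):
        return best_j
    admissible = np.flatnonzero(mean_scores >= best - se)
    return int(admissible[0])


def _coef_path(est: CoxnetSurvivalAnalysis, alphas: np.ndarray) -> np.ndarray:
    """Coefficients at each requested alpha, (n_features, n_alphas)."""
    fitted = np.asarray(est.alphas_)
    coefs = np.zeros((est.coef_.shape[0], alphas.size))
    for j, a in enumerate(alphas):
        k = int(np.argmin(np.abs(fitted - a)))
        coefs[:, j] = est.coef_[:, k]
    return coefs


def _penalty_grid(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    config: PrioritizationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalty grid and the coefficient path on the given design.

    ``"auto"`` derives the grid from the data: ``n_penalties`` log-spaced
    values from the smallest penalty zeroing every coefficient down
    ``penalty_min_ratio`` of it.  The returned path (features × alphas) is
    the fit on the full design, reused for the final per-iteration model.
    """
    if config.penalty_grid == "auto":
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=config.l1_ratio,
            n_alphas=config.n_penalties,
            alpha_min_ratio=config.penalty_min_ratio,
            fit_baseline_model=False,
        )
        probe.fit(X, Surv.from_arrays(event.astype(bool), time))
        return np.asarray(probe.alphas_), np.asarray(probe.coef_)
    alphas = np.sort(np.asarray(config.penalty_grid, dtype=float))[::-1]
    est = CoxnetSurvivalAnalysis(
        l1_ratio=config.l1_ratio, alphas=alphas, fit_baseline_model=False
    )
    est.fit(X, Surv.from_arrays(event.astype(bool), time))
    return alphas, _coef_path(est, alphas)


def stability_selection(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: GeneSet,
    config: PrioritizationConfig,
) -> SelectionResult:
    """Prioritize survival-associated genes over repeated subsampled fits.

    ``matrix`` should already have passed :func:`filter_expressed`.
    Deterministic given ``config.seed`` (per-iteration counter-based
    substreams, so B can change without reshuffling earlier iterations).
    Iterations whose penalized fit fails are dropped and counted; more than
    50% failures raises :class:`ProcedureError`.
    """
    gene_ids = genes.present_in(matrix)
    if not gene_ids:
        raise InputError(f"no member of gene set {genes.name!r} present in matrix")
    if clinical.event.sum() < 10:
        raise InputError("stability selection needs at least 10 events")

    features = log1p_features(matrix, gene_ids)  # samples x genes
    covs = _covariate_matrix(clinical, config.covariate_names)
    cov_names = list(config.covariate_names)
    time, event = clinical.time, clinical.event
    n = features.shape[0]
    m = max(2, int(round(config.subsample_fraction * n)))

    # complete cases with respect to the offered covariates
    complete = np.isfinite(covs).all(axis=1) if covs.size else np.ones(n, dtype=bool)
    features, covs = features[complete], covs[complete]
    time, event = time[complete], event[complete]
    n = features.shape[0]
    m = max(2, int(round(config.subsample_fraction * n)))

    if config.preselect_on_full_cohort:
        Xfull = _standardize_safe(features)
        _, _, full_p = cox_univariate_batch(Xfull, time, event)

    all_names = gene_ids + cov_names
    counts = pd.Series(0, index=all_names, dtype=float)
    completed = 0
    failed = 0

    for b in range(config.n_iterations):
        rng = _iteration_rng(config.seed, b)
        idx = rng.choice(n, size=m, replace=False)
        t_sub, e_sub = time[idx], event[idx]
        try:
            if e_sub.sum() < 2:
                raise FitError("subsample has fewer than 2 events")
            Xg = features[idx]
            sd = Xg.std(axis=0)
            usable = sd > 0
            Xg_std = np.zeros_like(Xg)
            Xg_std[:, usable] = (Xg[:, usable] - Xg[:, usable].mean(axis=0)) / sd[usable]

            if config.preselect_on_full_cohort:
                pre_mask = (full_p < config.preselect_alpha) & usable
            else:
                pvals = np.ones(len(gene_ids))
                if usable.any():
                    _, _, pvals_u = cox_univariate_batch(Xg_std[:, usable], t_sub, e_sub)
                    pvals[usable] = pvals_u
                pre_mask = pvals < config.preselect_alpha

            pre_genes = [g for g, keep in zip(gene_ids, pre_mask) if keep]
            cols = [Xg_std[:, pre_mask]] if pre_mask.any() else []
            names_b = list(pre_genes)
            if cov_names:
                C = covs[idx]
                csd = C.std(axis=0)
                c_ok = csd > 0
                C_std = np.zeros_like(C)
                C_std[:, c_ok] = (C[:, c_ok] - C[:, c_ok].mean(axis=0)) / csd[c_ok]
                cols.append(C_std[:, c_ok])
                names_b += [c for c, keep in zip(cov_names, c_ok) if keep]
            if not names_b:
                completed += 1  # nothing to offer; iteration records no feature
                continue
            Xb = np.hstack(cols)

            alphas, path = _penalty_grid(Xb, t_sub, e_sub, config)
            best_j = _cv_choose_alpha(
                Xg, covs[idx] if cov_names else np.empty((m, 0)),
                t_sub, e_sub, alphas, config, rng,
                fixed_pre_mask=pre_mask if config.preselect_on_full_cohort else None,
            )
            coef = path[:, best_j]
        except (FitError, ArithmeticError, ValueError) as exc:
            failed += 1
            continue
        completed += 1
        for name, c in zip(names_b, coef):
            if c != 0:
                counts[name] += 1

    if completed == 0 or failed > config.n_iterations / 2:
        raise ProcedureError(
            f"{failed}/{config.n_iterations} iterations failed; "
            "check event counts and feature variance"
        )

    frequencies = counts / completed
    selected = apply_selection_threshold(frequencies, config.selection_threshold)

    # univariate effect sizes on the full cohort (standardized features)
    Xfull_genes = _standardize_safe(features)
    beta_g, se_g, p_g = cox_univariate_batch(Xfull_genes, time, event)
    rows = {}
    for j, g in enumerate(gene_ids):
        rows[g] = ("gene", beta_g[j], se_g[j], p_g[j])
    if cov_names:
        Xfull_cov = _standardize_safe(covs)
        beta_c, se_c, p_c = cox_univariate_batch(Xfull_cov, time, event)
        for j, c in enumerate(cov_names):
            rows[c] = ("covariate", beta_c[j], se_c[j], p_c[j])

    table = pd.DataFrame(
        {
            "kind": [rows[f][0] for f in all_names],
            "selection_frequency": frequencies[all_names].to_numpy(),
            "selected": selected[all_names].to_numpy(),
            "log_hr": [rows[f][1] for f in all_names],
            "hr": [np.exp(rows[f][1]) for f in all_names],
            "hr_ci_low": [np.exp(rows[f][1] - 1.96 * rows[f][2]) for f in all_names],
            "hr_ci_high": [np.exp(rows[f][1] + 1.96 * rows[f][2]) for f in all_names],
            "wald_p": [rows[f][3] for f in all_names],
        },
        index=pd.Index(all_names, name="feature"),
    )
    return SelectionResult(
        table=table,
        n_iterations_completed=completed,
        n_iterations_failed=failed,
        config=config,
    )


def _standardize_safe(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    out = np.zeros_like(np.asarray(x, dtype=float))
    ok = sd > 0
    out[:, ok] = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    return out


# ---------------------------------------------------------------------------
# shuffled-outcome calibration
# ---------------------------------------------------------------------------

def shuffled_label_calibration(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: GeneSet,
    config: PrioritizationConfig,
    n_shuffles: int = 10,
    permutations: Sequence[np.ndarray] | None = None,
) -> CalibrationResult:
    """Stability selection on shuffled survival outcomes, next to the real run.

    Each shuffle permutes the ``(time, event)`` pairs jointly across samples
    while keeping expression profiles fixed, then re-runs
    :func:`stability_selection` with the same configuration (so an identity
    permutation reproduces the observed run exactly).  ``permutations``
    overrides the random permutations (mainly for testing).
    """
    observed = stability_selection(matrix, clinical, genes, config)
    n = len(clinical.sample_ids)
    if permutations is None:
        permutations = [
            _iteration_rng(config.seed, 1_000_000 + s).permutation(n)
            for s in range(n_shuffles)
        ]
    shuffled_results = []
    rows = [
        {
            "run": "observed",
            "n_selected_genes": len(observed.selected_genes()),
            "n_selected_covariates": len(observed.selected_covariates()),
            "n_iterations_failed": observed.n_iterations_failed,
        }
    ]
    for s, perm in enumerate(permutations):
        cdata = clinical.data.copy()
        cdata[["time", "event"]] = cdata[["time", "event"]].to_numpy()[np.asarray(perm)]
        shuffled_clinical = ClinicalTable(cdata, endpoint=clinical.endpoint)
        res = stability_selection(matrix, shuffled_clinical, genes, config)
        shuffled_results.append(res)
        rows.append(
            {
                "run": f"shuffle_{s}",
                "n_selected_genes": len(res.selected_genes()),
                "n_selected_covariates": len(res.selected_covariates()),
                "n_iterations_failed": res.n_iterations_failed,
            }
        )
    return CalibrationResult(
        observed=observed, shuffled=shuffled_results, table=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# multivariate vetting
# ---------------------------------------------------------------------------

def multivariate_vetting(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    candidate_genes: GeneSet,
    covariate_names: Sequence[str],
    *,
    condition_limit: float = 1e8,
) -> pd.DataFrame:
    """Adjusted hazard ratios for candidates in gene + covariates Cox models.

    One multivariate fit per candidate (standardized log1p gene expression
    plus the named covariates, complete cases), reporting the gene's
    adjusted HR, 95% CI and Wald p.  A near-singular design (condition
    number above ``condition_limit``) raises :class:`FitError` naming the
    collinear columns.
    """
    gene_ids = candidate_genes.present_in(matrix)
    if not gene_ids:
        raise InputError("no candidate gene present in matrix")
    covs = clinical.data[list(covariate_names)] if covariate_names else pd.DataFrame(index=clinical.data.index)
    rows = []
    for gene in gene_ids:
        feat = np.log1p(matrix.gene_values(gene))
        df = pd.DataFrame({"gene": feat}, index=clinical.data.index)
        for c in covariate_names:
            df[c] = covs[c].to_numpy(dtype=float)
        df["time"], df["event"] = clinical.time, clinical.event
        df = df.dropna()
        design = _standardize_safe(df[["gene", *covariate_names]].to_numpy(dtype=float))
        cond = np.linalg.cond(design.T @ design) if design.shape[1] > 1 else 1.0
        if not np.isfinite(cond) or cond > condition_limit:
            corr = np.corrcoef(design, rowvar=False)
            names = ["gene", *covariate_names]
            pairs = [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
                if abs(corr[i, j]) > 0.999
            ]
            raise FitError(f"collinear model columns for gene {gene!r}: {pairs or names}")
        df_fit = df.copy()
        df_fit["gene"] = (df_fit["gene"] - df_fit["gene"].mean()) / df_fit["gene"].std()
        cph = CoxPHFitter()
        try:
            cph.fit(df_fit, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            raise FitError(f"multivariate Cox fit failed for gene {gene!r}: {exc}") from exc
        log_hr = float(cph.params_["gene"])
        se = float(cph.standard_errors_["gene"])
        rows.append(
            {
                "gene_id": gene,
                "adjusted_log_hr": log_hr,
                "adjusted_hr": float(np.exp(log_hr)),
                "hr_ci_low": float(np.exp(log_hr - 1.96 * se)),
                "hr_ci_high": float(np.exp(log_hr + 1.96 * se)),
                "wald_p": float(cph.summary.loc["gene", "p"]),
                "n_complete": int(df_fit.shape[0]),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
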