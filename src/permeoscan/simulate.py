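"""Synthetic tumor cohorts with known ground truth.

Generates expression + survival cohorts carrying the statistical structure
the downstream analysis assumes, so every stage can be exercised against a
manifest of planted signals:

* baseline expression is log-normal (heavy-tailed, non-negative), per gene
  and sample;
* designated *outlier* genes have a random fraction of samples with
  fold-elevated expression;
* designated *switch-like* genes are zero except in a configured minority of
  samples, where they are log-normal;
* survival follows a proportional-hazards model: the hazard of sample *s*
  is ``baseline_hazard * exp(sum_g beta_g * z_g(s) + sum_c beta_c * c(s))``
  where ``z_g`` is the within-cohort standardized log1p expression of
  prognostic gene *g*.  Event times are exponential given the hazard;
  censoring times are independent uniform on ``(0, c_max)`` with ``c_max``
  calibrated by bisection so the realized censoring fraction lands within
  ±0.05 of the target.

One master seed drives counter-based substreams per component (baseline
expression, outlier assignment, switch assignment, covariates, survival,
censoring), so changing one configuration field does not perturb unrelated
draws, and identical configurations yield byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, ExpressionMatrix, InputError

__all__ = [
    "OutlierSpec",
    "SwitchSpec",
    "PrognosticSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationError",
    "simulate_cohort",
]

# substream indices of the master seed
_STREAM_BASELINE = 0
_STREAM_OUTLIER = 1
_STREAM_SWITCH = 2
_STREAM_COVARIATES = 3
_STREAM_SURVIVAL = 4
_STREAM_CENSORING = 5


class SimulationError(Exception):
    """The requested cohort cannot be generated (e.g., infeasible censoring)."""


@dataclass(frozen=True)
class OutlierSpec:
    """A gene with fold-elevated expression in a random sample fraction."""

    gene_index: int
    sample_fraction: float  # fraction of samples affected, in (0, 1)
    fold_change: float      # multiplicative elevation, >= 1


@dataclass(frozen=True)
class SwitchSpec:
    """A gene expressed only in a minority of samples (zero elsewhere)."""

    gene_index: int
    nonzero_fraction: float  # in (0, 0.5)
    nonzero_log_mean: float  # log-mean of expression where active


@dataclass(frozen=True)
class PrognosticSpec:
    """A gene whose standardized log1p expression carries a log hazard ratio."""

    gene_index: int
    beta: float  # log hazard ratio per standard deviation


@dataclass
class SimulationConfig:
    """Cohort generator settings.

    Defaults describe a mid-size tumor cohort: 300 samples (repository
    cohorts range from ~50 to a few hundred per cancer type), 200 genes,
    log-normal baseline expression with unit log-scale spread, a baseline
    hazard of 1/1000 events per day (median survival around two years) and a
    30% censoring target, typical of overall-survival follow-up.
    """

    n_samples: int = 300
    n_genes: int = 200
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    outlier_genes: Sequence[OutlierSpec] = field(default_factory=tuple)
    switch_genes: Sequence[SwitchSpec] = field(default_factory=tuple)
    prognostic_genes: Sequence[PrognosticSpec] = field(default_factory=tuple)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1e-3
    censoring_fraction_target: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise InputError("n_samples and n_genes must be positive")
        if self.baseline_log_sd <= 0 or self.baseline_hazard <= 0:
            raise InputError("baseline_log_sd and baseline_hazard must be positive")
        if not 0 <= self.censoring_fraction_target < 1:
            raise InputError("censoring_fraction_target must be in [0, 1)")
        for spec in list(self.outlier_genes) + list(self.switch_genes) + list(self.prognostic_genes):
            if not 0 <= spec.gene_index < self.n_genes:
                raise InputError(f"gene index {spec.gene_index} outside [0, {self.n_genes})")
        for spec in self.outlier_genes:
            if not 0 < spec.sample_fraction < 1:
                raise InputError("outlier sample_fraction must be in (0, 1)")
            if spec.fold_change < 1:
                raise InputError("outlier fold_change must be >= 1")
        for spec in self.switch_genes:
            if not 0 < spec.nonzero_fraction < 0.5:
                raise InputError("switch nonzero_fraction must be in (0, 0.5)")
        overlap = {s.gene_index for s in self.outlier_genes} & {s.gene_index for s in self.switch_genes}
        if overlap:
            raise InputError(f"genes designated both outlier and switch-like: {sorted(overlap)}")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest of one simulated cohort."""

    config: SimulationConfig
    gene_ids: list[str]
    sample_ids: list[str]
    outlier_masks: dict[str, np.ndarray]   # gene_id -> per-sample bool
    switch_masks: dict[str, np.ndarray]    # gene_id -> per-sample bool
    realized_censoring_fraction: float

    def prognostic_gene_ids(self) -> list[str]:
        return [self.gene_ids[s.gene_index] for s in self.config.prognostic_genes]

    def to_json(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        cfg["outlier_genes"] = [asdict(s) for s in self.config.outlier_genes]
        cfg["switch_genes"] = [asdict(s) for s in self.config.switch_genes]
        cfg["prognostic_genes"] = [asdict(s) for s in self.config.prognostic_genes]
        cfg["covariate_effects"] = dict(self.config.covariate_effects)
        payload = {
            "config": cfg,
            "gene_ids": self.gene_ids,
            "sample_ids": self.sample_ids,
            "outlier_samples": {g: np.flatnonzero(m).tolist() for g, m in self.outlier_masks.items()},
            "switch_samples": {g: np.flatnonzero(m).tolist() for g, m in self.switch_masks.items()},
            "realized_censoring_fraction": self.realized_censoring_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _calibrate_censoring(
    event_times: np.ndarray, uniforms: np.ndarray, target: float
) -> tuple[np.ndarray, float]:
    """Find a censoring window ``c_max`` so mean(T > c_max*U) ≈ target.

    The censoring fraction is monotone decreasing in ``c_max``; bisection on
    a bracketing interval converges to the achievable fraction nearest the
    target.  Returns the censoring times and the realized fraction.
    """

    def frac(c_max: float) -> float:
        return float(np.mean(event_times > c_max * uniforms))

    lo, hi = 1e-12, float(np.max(event_times)) * 2.0
    for _ in range(200):
        if frac(hi) <= target:
            break
        hi *= 4.0
    else:
        raise SimulationError("could not bracket the censoring target from above")
    for _ in range(200):
        if frac(lo) >= target:
            break
        lo /= 4.0
    for _ in range(100):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    c_max = hi
    realized = frac(c_max)
    if abs(realized - target) > 0.05:
        raise SimulationError(
            f"censoring target {target:.3f} infeasible: nearest achievable fraction {realized:.3f}"
        )
    return c_max * uniforms, realized


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate one cohort (expression, clinical, ground-truth manifest).

    Deterministic given ``config.seed``.  Covariates named ``sex`` are drawn
    Bernoulli(0.5) and coded 0/1; any other named covariate is drawn standard
    normal, so its effect is a log hazard ratio per standard deviation.
    """
    n, p = config.n_samples, config.n_genes
    gene_ids = [f"G{i:04d}" for i in range(p)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    expr = _rng(config.seed, _STREAM_BASELINE).lognormal(
        mean=config.baseline_log_mean, sigma=config.baseline_log_sd, size=(p, n)
    )

    rng_out = _rng(config.seed, _STREAM_OUTLIER)
    outlier_masks: dict[str, np.ndarray] = {}
    for spec in config.outlier_genes:
        mask = rng_out.random(n) < spec.sample_fraction
        expr[spec.gene_index, mask] *= spec.fold_change
        outlier_masks[gene_ids[spec.gene_index]] = mask

    rng_sw = _rng(config.seed, _STREAM_SWITCH)
    switch_masks: dict[str, np.ndarray] = {}
    for spec in config.switch_genes:
        mask = rng_sw.random(n) < spec.nonzero_fraction
        row = np.zeros(n)
        row[mask] = rng_sw.lognormal(mean=spec.nonzero_log_mean, sigma=config.baseline_log_sd, size=int(mask.sum()))
        expr[spec.gene_index] = row
        switch_masks[gene_ids[spec.gene_index]] = mask

    rng_cov = _rng(config.seed, _STREAM_COVARIATES)
    covariates = {}
    for name in config.covariate_effects:
        if name == "sex":
            covariates[name] = rng_cov.integers(0, 2, size=n).astype(float)
        else:
            covariates[name] = rng_cov.standard_normal(n)

    # linear predictor on standardized log1p expression of prognostic genes
    eta = np.zeros(n)
    for spec in config.prognostic_genes:
        feat = np.log1p(expr[spec.gene_index])
        sd = feat.std()
        if sd == 0:
            raise SimulationError(f"prognostic gene index {spec.gene_index} has zero variance")
        eta += spec.beta * (feat - feat.mean()) / sd
    for name, beta in config.covariate_effects.items():
        eta += beta * covariates[name]

    hazards = config.baseline_hazard * np.exp(eta)
    event_times = _rng(config.seed, _STREAM_SURVIVAL).exponential(1.0 / hazards)

    if config.censoring_fraction_target == 0:
        time, event = event_times, np.ones(n, dtype=int)
        realized = 0.0
    else:
        uniforms = np.clip(_rng(config.seed, _STREAM_CENSORING).random(n), 1e-12, None)
        censor_times, realized = _calibrate_censoring(
            event_times, uniforms, config.censoring_fraction_target
        )
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids), unit="arbitrary"
    )
    cdata = pd.DataFrame({"time": time, "event": event}, index=pd.Index(sample_ids, name="sample_id"))
    for name, vals in covariates.items():
        cdata[name] = vals
    clinical = ClinicalTable(cdata, endpoint="OS")
    truth = SyntheticTruth(
        config=config,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        outlier_masks=outlier_masks,
        switch_masks=switch_masks,
        realized_censoring_fraction=realized,
    )
    return matrix, clinical, truth
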