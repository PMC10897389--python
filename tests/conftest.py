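import numpy as np
import pandas as pd
import pytest

import permeoscan as ps


def make_matrix(values, gene_ids=None, sample_ids=None, unit="arbitrary"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[1])]
    return ps.ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), unit=unit)


def make_clinical(time, event, sample_ids=None, **covariates):
    time = np.asarray(time, dtype=float)
    sample_ids = sample_ids or [f"S{i}" for i in range(time.size)]
    data = pd.DataFrame(
        {"time": time, "event": np.asarray(event, dtype=int), **covariates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ps.ClinicalTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def prognostic_cohort():
    """Cohort with five planted prognostic genes (the parameter-recovery regime)."""
    cfg = ps.SimulationConfig(
        n_samples=300,
        n_genes=200,
        prognostic_genes=tuple(ps.PrognosticSpec(i, 0.7) for i in range(5)),
        censoring_fraction_target=0.3,
        seed=42,
    )
    return ps.simulate_cohort(cfg)
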