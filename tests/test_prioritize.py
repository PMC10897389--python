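"""Cox fits, expression filter, stability selection, calibration, vetting."""

import numpy as np
import pandas as pd
import pytest

import permeoscan as ps
from permeoscan.prioritize import apply_selection_threshold, cox_univariate_batch
from conftest import make_clinical, make_matrix
from oracles import grid_maximize_efron


class TestFilterExpressed:
    def test_low_and_boundary_genes_removed_strictly(self):
        matrix = make_matrix([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [1.5, 1.5, 1.5]])
        kept = ps.filter_expressed(matrix, 1.0)
        assert kept.gene_ids == ["G2"]  # mean == 1.0 removed (strict >)

    def test_matches_direct_row_mean_comparison(self, rng):
        matrix = make_matrix(rng.lognormal(0, 1, (50, 20)))
        kept = ps.filter_expressed(matrix, 1.0)
        expected = [g for g in matrix.gene_ids if matrix.gene_values(g).mean() > 1.0]
        assert kept.gene_ids == expected

    def test_all_removed_is_an_error(self):
        with pytest.raises(ps.InputError):
            ps.filter_expressed(make_matrix([[0.1, 0.2]]), 1.0)


class TestUnivariateCox:
    def test_exchangeable_groups_give_null_hazard(self):
        clinical = make_clinical([1.0, 1.0, 2.0, 2.0], [1, 1, 1, 1])
        log_hr, hr, ci, p = ps.univariate_coxph(np.array([0.0, 1.0, 0.0, 1.0]), clinical)
        assert log_hr == pytest.approx(0.0, abs=1e-8)
        assert hr == pytest.approx(1.0, abs=1e-8)
        assert ci[0] < 1 < ci[1]

    def test_matches_grid_efron_oracle_on_tiny_datasets(self, rng):
        for _ in range(6):
            n = int(rng.integers(5, 9))
            x = np.round(rng.standard_normal(n), 2)
            time = rng.integers(1, 5, n).astype(float)  # guarantees ties
            event = rng.integers(0, 2, n)
            if event.sum() < 2 or np.std(x) == 0:
                continue
            clinical = make_clinical(time, event)
            log_hr, _, _, _ = ps.univariate_coxph(x, clinical)
            oracle = grid_maximize_efron(x, time, event)
            if abs(oracle) > 7:  # monotone likelihood; no finite maximizer
                continue
            assert log_hr == pytest.approx(oracle, abs=1e-3)

    def test_batch_solver_agrees_with_lifelines_route(self, rng):
        n, p = 80, 5
        X = rng.standard_normal((n, p))
        time = (rng.exponential(50, n) + 1).round()
        event = rng.integers(0, 2, n)
        clinical = make_clinical(time, event)
        beta, se, pvals = cox_univariate_batch(X, time, event)
        for j in range(p):
            log_hr, _, ci, p_ref = ps.univariate_coxph(X[:, j], clinical)
            # lifelines' own convergence tolerance dominates the difference
            assert beta[j] == pytest.approx(log_hr, abs=1e-4)
            assert pvals[j] == pytest.approx(p_ref, rel=1e-3, abs=1e-8)

    def test_too_few_events_or_constant_feature_rejected(self):
        clinical = make_clinical([1, 2, 3, 4.0], [1, 0, 0, 0])
        with pytest.raises(ps.FitError):
            ps.univariate_coxph(np.array([1.0, 2, 3, 4]), clinical)
        clinical = make_clinical([1, 2, 3, 4.0], [1, 1, 1, 1])
        with pytest.raises(ps.FitError):
            ps.univariate_coxph(np.ones(4), clinical)


class TestStabilitySelection:
    def test_deterministic_given_seed(self, prognostic_cohort):
        matrix, clinical, _ = prognostic_cohort
        genes = ps.GeneSet("all", frozenset(matrix.gene_ids[:40]))
        config = ps.PrioritizationConfig(n_iterations=6, seed=11)
        filtered = ps.filter_expressed(matrix, 1.0)
        r1 = ps.stability_selection(filtered, clinical, genes, config)
        r2 = ps.stability_selection(filtered, clinical, genes, config)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.n_iterations_failed == r2.n_iterations_failed

    def test_frequencies_invariant_to_gene_order(self, prognostic_cohort):
        matrix, clinical, _ = prognostic_cohort
        filtered = ps.filter_expressed(matrix, 1.0)
        sub = filtered.gene_ids[:30]
        config = ps.PrioritizationConfig(n_iterations=6, seed=3)
        r1 = ps.stability_selection(filtered.subset_genes(sub), clinical,
                                    ps.GeneSet("a", frozenset(sub)), config)
        r2 = ps.stability_selection(filtered.subset_genes(sub[::-1]), clinical,
                                    ps.GeneSet("a", frozenset(sub)), config)
        f1 = r1.table["selection_frequency"].sort_index()
        f2 = r2.table["selection_frequency"].sort_index()
        pd.testing.assert_series_equal(f1, f2)

    def test_selection_threshold_is_strict(self):
        freq = pd.Series({"A": 0.5, "B": 0.51, "C": 0.49})
        selected = apply_selection_threshold(freq, 0.5)
        assert selected.to_dict() == {"A": False, "B": True, "C": False}

    def test_recovers_planted_prognostic_genes(self, prognostic_cohort):
        matrix, clinical, truth = prognostic_cohort
        genes = ps.GeneSet("all", frozenset(matrix.gene_ids))
        config = ps.PrioritizationConfig(n_iterations=40, seed=1)
        result = ps.stability_selection(ps.filter_expressed(matrix, 1.0), clinical, genes, config)
        selected = set(result.selected_genes())
        true_genes = set(truth.prognostic_gene_ids())
        assert len(selected & true_genes) >= 4
        null_rate = len(selected - true_genes) / (matrix.n_genes - len(true_genes))
        assert null_rate <= 0.05

    def test_monotone_power_in_effect_size(self):
        freqs = []
        for beta in (0.0, 0.35, 0.7, 1.0):
            cfg = ps.SimulationConfig(
                n_samples=150, n_genes=30, seed=8,
                prognostic_genes=(ps.PrognosticSpec(0, beta),) if beta else (),
                censoring_fraction_target=0.3,
            )
            matrix, clinical, _ = ps.simulate_cohort(cfg)
            config = ps.PrioritizationConfig(n_iterations=25, seed=4)
            result = ps.stability_selection(
                ps.filter_expressed(matrix, 1.0), clinical,
                ps.GeneSet("all", frozenset(matrix.gene_ids)), config,
            )
            freqs.append(result.table.loc["G0000", "selection_frequency"])
        assert all(b >= a - 1e-12 for a, b in zip(freqs, freqs[1:]))

    def test_empty_preselection_iterations_complete_without_genes(self, prognostic_cohort):
        matrix, clinical, _ = prognostic_cohort
        null_genes = ps.GeneSet("null", frozenset(matrix.gene_ids[10:40]))
        config = ps.PrioritizationConfig(n_iterations=5, seed=2, preselect_alpha=1e-12)
        result = ps.stability_selection(ps.filter_expressed(matrix, 1.0), clinical, null_genes, config)
        assert result.n_iterations_completed == 5
        assert (result.table["selection_frequency"] == 0).all()

    def test_too_few_events_rejected(self):
        matrix = make_matrix(np.random.default_rng(0).lognormal(1, 1, (5, 30)))
        clinical = make_clinical(np.arange(1.0, 31.0), [1] * 5 + [0] * 25)
        with pytest.raises(ps.InputError, match="10 events"):
            ps.stability_selection(matrix, clinical,
                                   ps.GeneSet("s", frozenset(matrix.gene_ids)),
                                   ps.PrioritizationConfig(n_iterations=2))


class TestShuffledCalibration:
    def test_identity_permutation_reproduces_observed_run(self, prognostic_cohort):
        matrix, clinical, _ = prognostic_cohort
        genes = ps.GeneSet("all", frozenset(matrix.gene_ids[:40]))
        config = ps.PrioritizationConfig(n_iterations=5, seed=6)
        filtered = ps.filter_expressed(matrix, 1.0)
        identity = np.arange(len(clinical.sample_ids))
        cal = ps.shuffled_label_calibration(
            filtered, clinical, genes, config, permutations=[identity]
        )
        pd.testing.assert_frame_equal(cal.observed.table, cal.shuffled[0].table)

    def test_shuffling_degrades_selection_of_true_genes(self, prognostic_cohort):
        matrix, clinical, truth = prognostic_cohort
        genes = ps.GeneSet("all", frozenset(matrix.gene_ids[:50]))
        config = ps.PrioritizationConfig(n_iterations=25, seed=13)
        cal = ps.shuffled_label_calibration(
            ps.filter_expressed(matrix, 1.0), clinical, genes, config, n_shuffles=2
        )
        observed = cal.table.loc[cal.table["run"] == "observed", "n_selected_genes"].iloc[0]
        assert observed > cal.shuffled_gene_counts().max()


class TestMultivariateVetting:
    def test_collinear_covariate_is_rejected_by_name(self, prognostic_cohort):
        matrix, clinical, _ = prognostic_cohort
        clin = clinical.data.copy()
        clin["dup"] = np.log1p(matrix.gene_values("G0000"))
        clinical2 = ps.ClinicalTable(clin)
        with pytest.raises(ps.FitError, match="collinear"):
            ps.multivariate_vetting(matrix, clinical2,
                                    ps.GeneSet("c", frozenset(["G0000"])), ["dup"])

    def test_confounded_gene_has_null_adjusted_hazard(self):
        """Survival depends only on age; a gene correlated with age should
        lose its effect once age is adjusted for."""
        covered = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = ps.SimulationConfig(
                n_samples=400, n_genes=5, seed=seed,
                covariate_effects={"age": 0.8}, censoring_fraction_target=0.2,
            )
            matrix, clinical, _ = ps.simulate_cohort(cfg)
            # manufacture the confounding: gene 0 tracks age plus noise
            rng = np.random.default_rng(seed)
            vals = matrix.values.copy()
            age = clinical.data["age"].to_numpy()
            vals.loc["G0000"] = np.exp(age + 0.5 * rng.standard_normal(age.size))
            matrix = ps.ExpressionMatrix(vals)
            table = ps.multivariate_vetting(matrix, clinical,
                                            ps.GeneSet("c", frozenset(["G0000"])), ["age"])
            lo, hi = table.loc["G0000", ["hr_ci_low", "hr_ci_high"]]
            if lo <= 1 <= hi:
                covered += 1
        assert covered >= 0.8 * n_rep

    def test_independent_gene_effect_survives_adjustment(self):
        cfg = ps.SimulationConfig(
            n_samples=1000, n_genes=10, seed=3,
            prognostic_genes=(ps.PrognosticSpec(0, 0.7),),
            covariate_effects={"age": 0.5}, censoring_fraction_target=0.2,
        )
        matrix, clinical, _ = ps.simulate_cohort(cfg)
        table = ps.multivariate_vetting(matrix, clinical,
                                        ps.GeneSet("c", frozenset(["G0000"])), ["age"])
        assert table.loc["G0000", "adjusted_log_hr"] == pytest.approx(0.7, rel=0.25)
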