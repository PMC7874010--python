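"""Tests for the Cox screen, stepwise BIC model, risk scores, KM/log-rank,
time-dependent ROC, and the LASSO comparator."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from fsor import (
    ClinicalTable,
    CoxScreenRow,
    ExpressionMatrix,
    SurvSimConfig,
    compare_pipelines,
    cox_partial_loglik,
    km_logrank,
    lasso_cox_baseline,
    published_luad_signature,
    risk_score,
    select_candidates,
    simulate_survival_cohort,
    stepwise_cox_bic,
    stratify_risk,
    time_dependent_roc,
    univariate_cox,
)
from fsor.prognosis import DAYS_PER_YEAR, RiskModel


def _cohort(**kw):
    return simulate_survival_cohort(SurvSimConfig(**kw))


class TestUnivariateCox:
    def test_null_design_type_one_error(self):
        cfg = SurvSimConfig(n_samples=200, n_genes=300, n_prognostic=0, seed=2)
        expr, clin, _ = simulate_survival_cohort(cfg)
        rows = univariate_cox(expr, clin)
        frac = np.mean([r.p <= 0.05 for r in rows])
        assert 0.01 <= frac <= 0.10  # ~5% expected under the null

    def test_recovers_single_gene_beta(self):
        betas = []
        for seed in range(5):
            cfg = SurvSimConfig(n_samples=400, n_genes=4, n_prognostic=1,
                                beta_range=(0.7, 0.7), seed=seed)
            expr, clin, truth = simulate_survival_cohort(cfg)
            gene = truth.genes.loc[truth.genes.true_beta > 0, "gene"].iloc[0]
            est = {r.gene: r.beta for r in univariate_cox(expr, clin)}
            betas.append(est[gene])
        assert abs(np.mean(betas) - 0.7) <= 0.15

    def test_affine_equivariance(self):
        expr, clin, _ = _cohort(n_samples=150, n_genes=3, n_prognostic=1, seed=9)
        rows1 = {r.gene: r for r in univariate_cox(expr, clin)}
        doubled = ExpressionMatrix(expr.values * 2.0, expr.gene_ids, expr.sample_ids)
        rows2 = {r.gene: r for r in univariate_cox(doubled, clin)}
        for g in rows1:
            assert rows2[g].beta == pytest.approx(rows1[g].beta * 0.5, rel=1e-6)
            assert rows2[g].p == pytest.approx(rows1[g].p, rel=1e-6)

    def test_preconditions(self, small_expression, small_clinical):
        with pytest.raises(ValueError):
            univariate_cox(
                ExpressionMatrix(small_expression.values[:, :4],
                                 small_expression.gene_ids,
                                 small_expression.sample_ids[:4]),
                ClinicalTable(small_clinical.sample_ids[:4],
                              small_clinical.time[:4], small_clinical.status[:4]),
            )


class TestSelectCandidates:
    @staticmethod
    def _row(gene, hr):
        return CoxScreenRow(gene, np.log(hr), hr, hr * 0.8, hr * 1.2, 0.5)

    def test_boundary_hr_included(self):
        assert select_candidates([self._row("a", 1.0)]) == ["a"]

    def test_published_screen_values_filtered(self):
        # univariate HRs reported for the 32-gene candidate screen: the six
        # risk-decreasing genes fall below the HR >= 1 rule
        hrs = {
            "CPSF3": 1.1262, "UNG": 1.4095, "CDCA8": 1.1656, "RCC2": 1.2477,
            "PLK1": 1.2994, "STX1A": 0.9996, "KAT2A": 0.8785, "MTA3": 0.9545,
            "GTF2IRD1": 0.8124, "HDAC10": 0.8455, "FOXRED1": 0.8799,
            "BRCA1": 1.1587,
        }
        rows = [self._row(g, h) for g, h in hrs.items()]
        kept = set(select_candidates(rows))
        assert kept == {g for g, h in hrs.items() if h >= 1.0}
        assert {"STX1A", "KAT2A", "MTA3", "GTF2IRD1", "HDAC10", "FOXRED1"}.isdisjoint(kept)

    def test_all_protective_gives_empty(self):
        assert select_candidates([self._row("a", 0.5), self._row("b", 0.9)]) == []


class TestStepwiseCoxBic:
    def test_strong_candidate_retained(self):
        for seed in range(3):
            expr, clin, truth = _cohort(n_samples=400, n_genes=1, n_prognostic=1,
                                        beta_range=(1.0, 1.0), seed=seed)
            gene = truth.genes["gene"].iloc[0]
            model = stepwise_cox_bic(expr, clin, [gene])
            assert model.genes == [gene]
            null_bic = -2 * cox_partial_loglik(clin.time, clin.status,
                                               np.zeros(clin.n))
            assert model.bic < null_bic

    def test_null_candidates_selected_sparsely(self):
        sizes = []
        for seed in range(10):
            expr, clin, _ = _cohort(n_samples=150, n_genes=10, n_prognostic=0,
                                    seed=100 + seed)
            model = stepwise_cox_bic(expr, clin, list(expr.gene_ids))
            sizes.append(len(model.genes))
        assert np.mean(sizes) <= 1

    def test_collinear_duplicate_ignored(self):
        expr, clin, truth = _cohort(n_samples=300, n_genes=3, n_prognostic=1,
                                    beta_range=(1.0, 1.0), seed=4)
        gene = truth.genes.loc[truth.genes.true_beta > 0, "gene"].iloc[0]
        dup = ExpressionMatrix(
            np.vstack([expr.values, expr.values[expr.gene_ids.index(gene)]]),
            expr.gene_ids + ["DUP"],
            expr.sample_ids,
        )
        base = stepwise_cox_bic(expr, clin, list(expr.gene_ids))
        with_dup = stepwise_cox_bic(dup, clin, list(expr.gene_ids) + ["DUP"])
        assert len(with_dup.genes) == len(base.genes)

    def test_candidate_order_invariance(self):
        expr, clin, _ = _cohort(n_samples=200, n_genes=8, n_prognostic=2, seed=21)
        rng = np.random.default_rng(0)
        base = stepwise_cox_bic(expr, clin, list(expr.gene_ids))
        for _ in range(4):
            perm = list(rng.permutation(expr.gene_ids))
            assert sorted(stepwise_cox_bic(expr, clin, perm).genes) == sorted(base.genes)

    def test_empty_candidates_rejected(self, small_expression, small_clinical):
        with pytest.raises(ValueError):
            stepwise_cox_bic(small_expression, small_clinical, [])


class TestRiskScore:
    def _unit_expr(self, genes, value):
        return ExpressionMatrix(
            np.full((len(genes), 2), value), list(genes), ["s1", "s2"]
        )

    def test_zero_expression_gives_zero_lp(self):
        model = published_luad_signature()
        scores = risk_score(model, self._unit_expr(model.genes, 0.0))
        assert np.all(scores["linear_predictor"] == 0)
        assert np.all(scores["relative_hazard"] == 1)

    def test_unit_expression_sums_published_weights(self):
        model = published_luad_signature()
        scores = risk_score(model, self._unit_expr(model.genes, 1.0))
        expected = 1.1168 + 0.4740 + 1.4432 + 1.7456 + 1.6966 + 1.1153 + 0.6784 + 1.3090
        assert scores["linear_predictor"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_single_gene_increment(self):
        model = published_luad_signature()
        X0 = self._unit_expr(model.genes, 1.0)
        bumped = X0.values.copy()
        bumped[model.genes.index("PLK1")] += 1.0
        X1 = ExpressionMatrix(bumped, list(model.genes), ["s1", "s2"])
        lp0 = risk_score(model, X0)["linear_predictor"].iloc[0]
        lp1 = risk_score(model, X1)["linear_predictor"].iloc[0]
        assert lp1 - lp0 == pytest.approx(1.7456, abs=1e-12)

    def test_log_hr_weighting_option(self):
        model = published_luad_signature(weighting="log_hr")
        np.testing.assert_allclose(model.coefficients, np.log(model.hrs))

    def test_missing_gene_rejected(self):
        model = published_luad_signature()
        with pytest.raises(KeyError):
            risk_score(model, self._unit_expr(["RACGAP1"], 1.0))


class TestStratifyRisk:
    def test_median_split(self):
        labels = stratify_risk([1.0, 2.0, 3.0, 4.0])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_tie_goes_low(self):
        labels = stratify_risk([1.0, 2.0, 2.0, 5.0])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stratify_risk([1.0])
        with pytest.raises(ValueError):
            stratify_risk([2.0, 2.0, 2.0])


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [50.0, 120, 300, 400, 80]
        status = [1, 0, 1, 1, 0]
        clin = ClinicalTable(
            [f"p{i}" for i in range(10)], times + times, status + status
        )
        _, chi2, p = km_logrank(clin, ["a"] * 5 + ["b"] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_two_group_toy(self):
        # A=(6,7,10), B=(8,9,11), all events; observed-minus-expected over the
        # six distinct event times gives U=1.016667, Var=1.149722
        clin = ClinicalTable(list("abcdef"), [6.0, 7, 10, 8, 9, 11], [1] * 6)
        groups = ["A", "A", "A", "B", "B", "B"]
        _, chi2, _ = km_logrank(clin, groups)
        u = 3 - (0.5 + 0.4 + 0.25 + 1 / 3 + 0.5)
        var = 0.25 + 0.24 + 0.1875 + 2 / 9 + 0.25
        assert chi2 == pytest.approx(u * u / var, abs=1e-6)

    def test_product_limit_steps(self):
        clin = ClinicalTable(["a", "b"], [5.0, 10.0], [1, 1])
        curves, _, _ = km_logrank(
            ClinicalTable(["a", "b", "c", "d"], [5.0, 10, 5, 10], [1, 1, 1, 1]),
            ["g1", "g1", "g2", "g2"],
        )
        s = curves["g1"].iloc[:, 0]
        np.testing.assert_allclose(s.values, [1.0, 0.5, 0.0])

    def test_group_label_swap_invariant(self, small_clinical):
        g = ["a"] * 5 + ["b"] * 5
        swapped = ["b"] * 5 + ["a"] * 5
        _, chi1, p1 = km_logrank(small_clinical, g)
        _, chi2, p2 = km_logrank(small_clinical, swapped)
        assert chi1 == pytest.approx(chi2)
        assert p1 == pytest.approx(p2)


class TestTimeDependentRoc:
    def test_perfect_ranking_gives_auc_one(self):
        n = 40
        times = np.linspace(30, 4 * DAYS_PER_YEAR + 200, n)
        clin = ClinicalTable([f"p{i}" for i in range(n)], times, np.ones(n, int))
        for h in (1, 2, 3):
            roc = time_dependent_roc(-times, clin, h)
            assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_uncensored_limit_matches_plain_roc(self, rng):
        n = 120
        times = rng.uniform(30, 6 * DAYS_PER_YEAR, n)
        clin = ClinicalTable([f"p{i}" for i in range(n)], times, np.ones(n, int))
        scores = rng.normal(size=n)
        for h in (1, 3):
            roc = time_dependent_roc(scores, clin, h)
            labels = (times <= h * DAYS_PER_YEAR).astype(int)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_agrees_with_external_ipcw_estimator_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        expr, clin, truth = _cohort(seed=6)
        scores = truth.linear_predictor.to_numpy()
        y = Surv.from_arrays(clin.status.astype(bool), clin.time)
        for h in (1, 2, 3):
            ours = time_dependent_roc(scores, clin, h).auc
            ref = float(
                cumulative_dynamic_auc(y, y, scores, [h * DAYS_PER_YEAR])[0][0]
            )
            assert ours == pytest.approx(ref, abs=0.02)

    def test_roc_endpoints(self):
        expr, clin, truth = _cohort(seed=8)
        roc = time_dependent_roc(truth.linear_predictor.to_numpy(), clin, 2)
        assert 0.0 <= roc.auc <= 1.0
        assert (roc.sensitivity[0], roc.specificity[0]) == (0.0, 1.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1.0, 0.0)

    def test_horizon_beyond_followup_rejected(self, small_clinical):
        with pytest.raises(ValueError):
            time_dependent_roc(np.arange(10), small_clinical, 50)


class TestLassoCox:
    def test_full_shrinkage_gives_empty_model(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        expr, clin, _ = _cohort(seed=1)
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e6])
        m.fit(expr.values.T, Surv.from_arrays(clin.status.astype(bool), clin.time))
        assert np.all(np.asarray(m.coef_) == 0)

    def test_planted_genes_selected(self):
        expr, clin, truth = _cohort(seed=11)
        model = lasso_cox_baseline(expr, clin, seed=11)
        planted = set(truth.genes.loc[truth.genes.true_beta > 0, "gene"])
        assert len(planted & set(model.genes)) >= 3

    def test_seeded_determinism(self):
        expr, clin, _ = _cohort(seed=13)
        m1 = lasso_cox_baseline(expr, clin, seed=13)
        m2 = lasso_cox_baseline(expr, clin, seed=13)
        assert m1.genes == m2.genes
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)


class TestComparePipelines:
    def test_shape_and_determinism(self):
        expr, clin, _ = _cohort(n_samples=200, n_genes=40, seed=17)
        comp = compare_pipelines(expr, clin, top_m=20, seed=17)
        assert len(comp.per_horizon) == 8  # 4 horizons x 2 methods
        assert set(comp.per_horizon["method"]) == {"fsor_cox", "lasso_cox"}
        assert set(comp.per_horizon["horizon_years"]) == {1, 2, 3, 4}
        comp2 = compare_pipelines(expr, clin, top_m=20, seed=17)
        np.testing.assert_array_equal(
            comp.per_horizon["auc"].to_numpy(), comp2.per_horizon["auc"].to_numpy()
        )

    def test_identical_scores_give_identical_auc_rows(self):
        """Harness symmetry: the same risk model scored twice gives the same AUC."""
        expr, clin, truth = _cohort(seed=19)
        genes = truth.genes.loc[truth.genes.true_beta > 0, "gene"].tolist()
        betas = truth.genes.loc[truth.genes.true_beta > 0, "true_beta"].to_numpy()
        model = RiskModel(genes, betas, np.exp(betas))
        s = risk_score(model, expr)["linear_predictor"].to_numpy()
        a1 = [time_dependent_roc(s, clin, h).auc for h in (1, 2, 3, 4)]
        a2 = [time_dependent_roc(s, clin, h).auc for h in (1, 2, 3, 4)]
        assert a1 == a2


class TestPartialLoglik:
    def test_matches_lifelines_at_fitted_beta(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        expr, clin, _ = _cohort(n_samples=150, n_genes=2, n_prognostic=1, seed=3)
        df = pd.DataFrame(expr.values.T, columns=expr.gene_ids)
        df["time"], df["status"] = clin.time, clin.status
        cph = CoxPHFitter().fit(df, "time", "status")
        lp = expr.values.T @ cph.params_.to_numpy()
        ours = cox_partial_loglik(clin.time, clin.status, lp)
        assert ours == pytest.approx(float(cph.log_likelihood_), rel=1e-9)
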