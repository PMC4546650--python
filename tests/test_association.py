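"""Association fits: the TC transform, the fasting rule, exact noise-free
limits, OLS collapse, model-level collapse, covariate screens and the
order/scale invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from demostrat.association import (covariate_effect_test, dichotomize_fasting,
                                   fit_additive_baseline,
                                   fit_additive_batch,
                                   fit_additive_cumulative, transform_tc)
from demostrat.exceptions import DegeneratePredictorError, InputError
from demostrat.synthetic import (SnpSpec, default_effect_model,
                                 simulate_genotypes, simulate_pedigree,
                                 simulate_phenotypes)
from conftest import BASELINE_SCHEDULE, REPEATED_G2_SCHEDULE, make_cohort


class TestTransform:
    @pytest.mark.parametrize("tc,expected", [
        (100.0, 200.0), (1000.0, 300.0), (194.0, 228.78)])
    def test_known_values(self, tc, expected):
        assert transform_tc(tc) == pytest.approx(expected, abs=0.01)

    def test_rejects_non_positive(self):
        with pytest.raises(InputError):
            transform_tc(0.0)
        with pytest.raises(InputError):
            transform_tc(np.array([150.0, -1.0]))

    @given(st.floats(1.0, 1000.0), st.floats(1.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a < b:
            assert transform_tc(a) < transform_tc(b)


class TestFastingRule:
    @pytest.mark.parametrize("hours,expected", [
        (12.0, True), (16.0, True), (np.nan, True), (11.5, False),
        (0.0, False)])
    def test_dichotomization(self, hours, expected):
        assert dichotomize_fasting(hours) is expected

    def test_negative_hours_rejected(self):
        with pytest.raises(InputError):
            dichotomize_fasting(-1.0)

    def test_vectorised(self):
        out = dichotomize_fasting([8.0, 12.0, np.nan])
        np.testing.assert_array_equal(out, [False, True, True])


def _uniform_model(beta_snp=0.0, **kw):
    """All cells share one intercept so additive covariates span the mean
    structure exactly (needed for machine-precision limits)."""
    model = default_effect_model(age_slope=0.0, **kw)
    mu = np.mean(list(model.intercept.values()))
    for key in model.intercept:
        model.intercept[key] = mu
    if beta_snp:
        for sex in "MW":
            for gen in (1, 2, 3):
                model.beta[("snp", sex, gen, "all")] = beta_snp
    return model


class TestBaselineFit:
    def test_noise_free_recovery_is_exact(self):
        model = _uniform_model(beta_snp=0.5)
        model.sigma2_family = model.sigma2_subject = 0.0
        model.sigma2_residual = 0.0
        ped = simulate_pedigree(30, seed=1)
        geno = simulate_genotypes(ped, [SnpSpec("snp", 0.3)], seed=2)
        pheno = simulate_phenotypes(ped, geno, model, BASELINE_SCHEDULE,
                                    seed=3)
        res = fit_additive_baseline(pheno, geno, "snp")
        assert res.beta == pytest.approx(0.5, abs=1e-6)

    def test_single_member_families_match_ols(self):
        """With unrelated individuals the mixed model must reduce to
        ordinary least squares on the same design."""
        rng = np.random.default_rng(5)
        n = 500
        dosage = rng.binomial(2, 0.3, n).astype(float)
        age = rng.normal(45, 8, n)
        y = 228 + 0.6 * dosage + 0.1 * age + rng.normal(0, 8, n)
        pheno = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(n)],
            "family_id": [f"f{k}" for k in range(n)],
            "sex": "M", "generation": 2, "exam_index": 1,
            "age_at_exam": age, "tc_mgdl": 10 ** (y / 100.0),
            "fasting_hours": 13.0, "lipid_treatment": False, "wga": False})
        geno = pd.DataFrame({"snp": dosage},
                            index=pd.Index(pheno.individual_id,
                                           name="individual_id"))
        res = fit_additive_baseline(pheno, geno, "snp", covariates=("age",))
        X = np.column_stack([np.ones(n), dosage, age])
        # oracle: closed-form OLS on the identically ordered design
        order = np.lexsort((pheno.individual_id.to_numpy(),
                            pheno.family_id.to_numpy()))
        Xo, yo = X[order], y[order]
        beta = np.linalg.solve(Xo.T @ Xo, Xo.T @ yo)
        assert res.beta == pytest.approx(beta[1], abs=1e-6)

    def test_constant_dosage_rejected(self, small_cohort):
        ped, geno, pheno = small_cohort
        flat = geno.copy()
        flat["snp0"] = 1.0
        with pytest.raises(DegeneratePredictorError):
            fit_additive_baseline(pheno, flat, "snp0")

    def test_unknown_snp_rejected(self, small_cohort):
        _, geno, pheno = small_cohort
        with pytest.raises(InputError):
            fit_additive_baseline(pheno, geno, "rs0")

    def test_record_order_invariance(self, small_cohort):
        _, geno, pheno = small_cohort
        shuffled = pheno.sample(frac=1.0, random_state=3,
                                ignore_index=True)
        a = fit_additive_baseline(pheno, geno, "rs2479409")
        b = fit_additive_baseline(shuffled, geno, "rs2479409")
        assert (a.beta, a.se, a.p_value) == (b.beta, b.se, b.p_value)

    def test_scale_equivariance(self, small_cohort):
        """Multiplying the (raw-scale) phenotype by c multiplies beta and
        SE by c and leaves p unchanged."""
        _, geno, pheno = small_cohort
        c = 3.7
        scaled = pheno.assign(tc_mgdl=pheno.tc_mgdl * c)
        a = fit_additive_baseline(pheno, geno, "rs3764261", scale="raw")
        b = fit_additive_baseline(scaled, geno, "rs3764261", scale="raw")
        assert b.beta == pytest.approx(c * a.beta, rel=1e-8)
        assert b.se == pytest.approx(c * a.se, rel=1e-8)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-8)

    def test_wald_p_self_consistency(self, small_cohort):
        from scipy import stats
        _, geno, pheno = small_cohort
        res = fit_additive_baseline(pheno, geno, "rs1564348")
        assert res.p_value == pytest.approx(
            2 * stats.norm.sf(abs(res.beta / res.se)), rel=1e-12)


class TestCumulativeFit:
    def test_collapses_to_baseline_with_single_exam(self):
        """One record per person makes the three-level model identical to
        the two-level baseline fit."""
        ped, geno, pheno = make_cohort(n_families=50, seed=17,
                                       schedule=BASELINE_SCHEDULE)
        a = fit_additive_baseline(pheno, geno, "rs2479409")
        b = fit_additive_cumulative(pheno, geno, "rs2479409")
        assert b.beta == pytest.approx(a.beta, abs=1e-6)
        assert b.se == pytest.approx(a.se, abs=1e-6)

    def test_repeated_measures_reduce_se(self):
        """Using all exams typically tightens the SE versus baseline."""
        wins = 0
        for seed in range(20):
            _, geno, pheno = make_cohort(
                n_families=80, scenario="homogeneous", beta=0.4, seed=seed,
                snps=[SnpSpec("snp", 0.3)], schedule=REPEATED_G2_SCHEDULE)
            g2 = pheno[pheno.generation == 2]
            a = fit_additive_baseline(g2, geno, "snp",
                                      covariates=("age", "sex"))
            b = fit_additive_cumulative(g2, geno, "snp",
                                        covariates=("age", "sex"))
            wins += b.se <= a.se
        assert wins >= 18

    def test_batch_results_match_single_fits(self, clustered_cohort):
        _, geno, pheno = clustered_cohort
        batch = dict(fit_additive_batch(pheno, geno,
                                        ["rs2479409", "rs1800562"],
                                        model_level="three_level"))
        for snp_id, res in batch.items():
            single = fit_additive_cumulative(pheno, geno, snp_id)
            assert (res.beta, res.se) == (single.beta, single.se)


class TestCovariateScreen:
    def test_planted_treatment_shift_recovered(self):
        """A +10 mg/dL treatment shift is recovered within 2 SE."""
        hits = 0
        for seed in range(20):
            model = default_effect_model()
            # plant the shift on the transformed scale at the cohort mean
            model.treatment_effect = transform_tc(205.0) - transform_tc(195.0)
            ped = simulate_pedigree(140, seed=seed)
            geno = simulate_genotypes(ped, [SnpSpec("s", 0.3)],
                                      seed=seed + 1)
            pheno = simulate_phenotypes(ped, geno, model, BASELINE_SCHEDULE,
                                        seed=seed + 2)
            g2 = pheno[pheno.generation == 2]
            res = covariate_effect_test(g2, "treatment")
            hits += abs(res.beta - model.treatment_effect) <= 2 * res.se
        assert hits >= 18

    def test_single_level_covariate_rejected(self, small_cohort):
        _, _, pheno = small_cohort
        allon = pheno.assign(lipid_treatment=True)
        with pytest.raises(DegeneratePredictorError):
            covariate_effect_test(allon, "treatment")

    def test_fasting_screen_runs(self, small_cohort):
        _, _, pheno = small_cohort
        res = covariate_effect_test(pheno[pheno.generation == 2], "fasting")
        assert res.snp_id == "fasting" and res.se > 0
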