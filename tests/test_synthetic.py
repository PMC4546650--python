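"""Synthetic cohort generator: pedigree structure, Mendelian genotypes,
Hardy-Weinberg founders, phenotype calibration and scenario profiles."""

import numpy as np
import pytest
from scipy import stats

from demostrat.exceptions import ConfigurationError, InputError
from demostrat.synthetic import (DEFAULT_SNPS, EffectModel, ExamSchedule,
                                 SnpSpec, default_effect_model,
                                 lognormal_calibration, scenario_library,
                                 simulate_genotypes, simulate_pedigree,
                                 simulate_phenotypes, TC_TARGETS)
from conftest import BASELINE_SCHEDULE, make_cohort


class TestPedigree:
    def test_minimal_family_structure(self):
        ped = simulate_pedigree(1, offspring=1, seed=7)
        df = ped.df
        assert len(df[df.generation == 1]) == 2
        # one child + one married-in spouse at generation 2
        g2 = df[df.generation == 2]
        assert len(g2) == 2
        assert g2.father_id.notna().sum() == 1
        assert len(df[df.generation == 3]) == 1
        ped.validate()

    def test_generation2_birth_years_follow_cohort_target(self):
        ped = simulate_pedigree(500, offspring=("poisson", 2, 1), seed=1)
        df = ped.df
        g2 = df[(df.generation == 2) & df.father_id.notna()]
        assert g2.birth_year.mean() == pytest.approx(1937, abs=2)

    def test_seeded_determinism(self):
        a = simulate_pedigree(40, seed=3).df
        b = simulate_pedigree(40, seed=3).df
        assert a.equals(b)

    def test_spouses_are_founders_sharing_family_id(self):
        df = simulate_pedigree(20, seed=5).df
        spouses = df[(df.generation > 1) & df.father_id.isna()]
        assert len(spouses) > 0
        assert spouses.mother_id.isna().all()
        assert set(spouses.family_id) <= set(df.family_id)

    def test_invalid_family_count_rejected(self):
        with pytest.raises(InputError):
            simulate_pedigree(0, seed=1)

    def test_survival_thinning_blanks_generation1_ages(self):
        ped = simulate_pedigree(100, seed=2, survival_thinning=0.5)
        g1 = ped.df[ped.df.generation == 1]
        assert 0 < g1.age_at_biospecimen.isna().sum() < len(g1)


class TestGenotypes:
    def test_mendelian_consistency_exact(self):
        """Every trio's child dosage lies inside the parental bounds."""
        ped, geno, _ = make_cohort(n_families=40, seed=13,
                                   schedule=BASELINE_SCHEDULE)
        df = ped.df
        G = geno.to_numpy()
        pos = {i: k for k, i in enumerate(df.individual_id)}
        trios = df[df.father_id.notna()]
        c = G[[pos[i] for i in trios.individual_id]]
        f = G[[pos[i] for i in trios.father_id]]
        m = G[[pos[i] for i in trios.mother_id]]
        lo = (f == 2).astype(int) + (m == 2).astype(int)
        hi = 2 - (f == 0).astype(int) - (m == 0).astype(int)
        assert ((c >= lo) & (c <= hi)).all()

    def test_homozygous_parents_force_children(self):
        ped = simulate_pedigree(30, seed=3)
        geno = simulate_genotypes(ped, [SnpSpec("s", 0.4)], seed=4)
        df = ped.df
        trios = df[df.father_id.notna()]
        g = geno["s"]
        both0 = trios[(g[trios.father_id].to_numpy() == 0)
                      & (g[trios.mother_id].to_numpy() == 0)]
        assert (g[both0.individual_id] == 0).all()
        both2 = trios[(g[trios.father_id].to_numpy() == 2)
                      & (g[trios.mother_id].to_numpy() == 2)]
        assert (g[both2.individual_id] == 2).all()

    def test_founder_maf_and_hwe(self):
        """Founder sample MAF near spec and HWE chi-square not rejected."""
        ped = simulate_pedigree(1000, seed=5)     # 2000+ founders
        geno = simulate_genotypes(ped, [SnpSpec("rs2479409", 0.34)], seed=6)
        founders = geno.loc[ped.founders.individual_id, "rs2479409"]
        maf = founders.mean() / 2
        assert maf == pytest.approx(0.34, abs=0.02)
        n = len(founders)
        counts = np.bincount(founders.astype(int), minlength=3)
        p = maf
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        assert stats.chi2.sf(chi2, 1) > 0.001

    def test_invalid_maf_rejected(self):
        with pytest.raises(InputError):
            SnpSpec("bad", 0.6)
        with pytest.raises(InputError):
            SnpSpec("bad", 0.0)

    def test_missing_rate_produces_nans(self):
        ped = simulate_pedigree(50, seed=1)
        geno = simulate_genotypes(ped, [SnpSpec("s", 0.3)], seed=2,
                                  missing_rate=0.1)
        frac = geno["s"].isna().mean()
        assert 0.05 < frac < 0.15


class TestPhenotypes:
    def test_noise_free_limit_is_exact(self):
        """With all variances, slopes and effects zero, TC equals the
        back-transformed cell intercept to machine precision."""
        model = default_effect_model(age_slope=0.0)
        model.sigma2_family = model.sigma2_subject = 0.0
        model.sigma2_residual = 0.0
        ped, geno, _ = make_cohort(n_families=10, seed=3,
                                   schedule=BASELINE_SCHEDULE)
        pheno = simulate_phenotypes(ped, geno, model, BASELINE_SCHEDULE,
                                    seed=4)
        for (sex, gen), mu in model.intercept.items():
            cell = pheno[(pheno.sex == sex) & (pheno.generation == gen)]
            np.testing.assert_allclose(cell.tc_mgdl, 10 ** (mu / 100.0),
                                       rtol=1e-12)

    def test_generation3_male_mean_matches_cohort_target(self):
        """Cell intercepts calibrated to the demographic targets reproduce
        the raw-scale mean (averaged over a few seeds to tame the familial
        clustering of the cell mean)."""
        means = []
        for seed in range(5):
            _, _, pheno = make_cohort(n_families=390, seed=100 + seed,
                                      schedule=BASELINE_SCHEDULE)
            cell = pheno[(pheno.generation == 3) & (pheno.sex == "M")]
            assert len(cell) > 1500
            means.append(cell.tc_mgdl.mean())
        assert np.mean(means) == pytest.approx(192.8, abs=2.0)

    def test_family_effects_induce_sibling_correlation(self):
        """Within-family correlation of subject means exceeds that of a
        permuted (family-broken) pairing."""
        model = default_effect_model()
        ped, geno, _ = make_cohort(n_families=500, seed=21,
                                   schedule=BASELINE_SCHEDULE)
        pheno = simulate_phenotypes(ped, geno, model, BASELINE_SCHEDULE,
                                    seed=22)
        g3 = pheno[pheno.generation == 3].copy()
        g3["t"] = 100 * np.log10(g3.tc_mgdl)
        # pair two siblings per family
        sib = g3.groupby("family_id").filter(lambda d: len(d) >= 2)
        first = sib.groupby("family_id")["t"].nth(0).to_numpy()
        second = sib.groupby("family_id")["t"].nth(1).to_numpy()
        r_fam = np.corrcoef(first, second)[0, 1]
        rng = np.random.default_rng(0)
        r_perm = np.corrcoef(first, rng.permutation(second))[0, 1]
        assert r_fam > 0.05
        assert r_fam > r_perm

    def test_repeated_records_share_subject_effect(self):
        """Within-person variance across exams is far below the total."""
        _, _, pheno = make_cohort(n_families=50, seed=31)
        g2 = pheno[pheno.generation == 2].copy()
        g2["t"] = 100 * np.log10(g2.tc_mgdl)
        within = g2.groupby("individual_id")["t"].var().mean()
        total = g2["t"].var()
        assert within < 0.6 * total

    def test_missing_effect_cell_raises(self):
        model = default_effect_model()
        del model.intercept[("M", 3)]
        ped, geno, _ = make_cohort(n_families=5, seed=3,
                                   schedule=BASELINE_SCHEDULE)
        with pytest.raises(ConfigurationError):
            simulate_phenotypes(ped, geno, model, seed=1)

    def test_exam_schedule_respected(self):
        _, _, pheno = make_cohort(n_families=20, seed=41)
        per_gen = pheno.groupby("generation")["exam_index"].max()
        assert per_gen[1] == 16 and per_gen[2] == 7 and per_gen[3] == 1
        # biennial vs quadrennial spacing
        g1 = pheno[pheno.generation == 1].groupby("individual_id")
        ages = g1["age_at_exam"].agg(lambda a: np.diff(np.sort(a)).mean())
        assert np.allclose(ages.dropna(), 2.0)


class TestCalibration:
    def test_lognormal_moment_matching_is_exact(self):
        rng = np.random.default_rng(1)
        mu, sigma = lognormal_calibration(194.0, 38.0)
        t = rng.normal(mu, sigma, 400_000)
        tc = 10 ** (t / 100.0)
        assert tc.mean() == pytest.approx(194.0, rel=2e-3)
        assert tc.std() == pytest.approx(38.0, rel=1e-2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            lognormal_calibration(-1, 38)


class TestScenarioLibrary:
    def test_homogeneous_effect_is_uniform(self):
        model = scenario_library("homogeneous", beta=1.5)
        betas = {model.beta_for("rs2479409", s, g, "all")
                 for s in "MW" for g in (1, 2, 3)}
        assert betas == {1.5}

    def test_antagonistic_reverses_younger_generation3(self):
        model = scenario_library("antagonistic", beta=2.0)
        assert model.beta_for("rs2479409", "W", 3, "younger") == -2.0
        assert model.beta_for("rs2479409", "W", 3, "older") == 2.0
        assert model.beta_for("rs2479409", "M", 1, "all") == 2.0

    def test_generation_clustered_confined_to_youngest(self):
        model = scenario_library("generation_clustered", beta=2.0)
        for sex in "MW":
            assert model.beta_for("rs1800562", sex, 3, "all") == 2.0
            assert model.beta_for("rs1800562", sex, 1, "all") == 0.0
            assert model.beta_for("rs1800562", sex, 2, "all") == 0.0

    def test_unknown_scenario_raises(self):
        with pytest.raises(LookupError):
            scenario_library("nonesuch")
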