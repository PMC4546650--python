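"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from demostrat.synthetic import (DEFAULT_SNPS, ExamSchedule, SnpSpec,
                                 scenario_library, simulate_genotypes,
                                 simulate_pedigree, simulate_phenotypes)

#: exam schedule with a single baseline visit per generation — cheap to
#: simulate and sufficient for baseline-model tests.
BASELINE_SCHEDULE = ExamSchedule({1: (1, 2.0), 2: (1, 4.0), 3: (1, 0.0)})

#: schedule keeping repeated measurements only where the cumulative model
#: uses them in tests (generation 2).
REPEATED_G2_SCHEDULE = ExamSchedule({1: (1, 2.0), 2: (7, 4.0), 3: (1, 0.0)})


def make_cohort(n_families=60, scenario="homogeneous", beta=0.0, seed=0,
                snps=None, schedule=None, **pheno_kwargs):
    """Pedigree + genotypes + phenotypes under a named scenario."""
    snps = snps if snps is not None else DEFAULT_SNPS
    model = scenario_library(scenario, beta=beta, snps=snps)
    ped = simulate_pedigree(n_families, seed=seed)
    geno = simulate_genotypes(ped, snps, seed=seed + 1)
    pheno = simulate_phenotypes(ped, geno, model, schedule, seed=seed + 2,
                                **pheno_kwargs)
    return ped, geno, pheno


@pytest.fixture(scope="session")
def small_cohort():
    """60 families, null effects, full default exam schedules."""
    return make_cohort(n_families=60, seed=7)


@pytest.fixture(scope="session")
def clustered_cohort():
    """85 families with effects confined to generation 3."""
    return make_cohort(n_families=85, scenario="generation_clustered",
                       beta=2.0, seed=11)


@pytest.fixture(scope="session")
def single_snp():
    return [SnpSpec("snp", 0.30)]
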