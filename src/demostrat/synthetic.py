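"""Synthetic three-generation family cohorts with genotypes and repeated
total-cholesterol measurements.

The generator emulates the structure of a classic multi-generation
cardiovascular cohort: an original generation recruited mid-20th century and
examined biennially over decades, their offspring (and the offspring's
spouses) examined roughly every four years, and a third generation with a
single baseline examination.  Genotypes for unlinked SNPs are drawn in
Hardy-Weinberg equilibrium for founders and transmitted Mendelianly to
descendants.  The quantitative phenotype is total cholesterol (TC, mg/dL),
generated additively on the 100*log10 scale from demographic-cell
intercepts, an age slope, per-SNP allele-dosage effects that may differ by
sex, generation and age stratum, and family / subject / residual Gaussian
components, then back-transformed to mg/dL.  Cell intercepts are calibrated
by log-normal moment matching so that the simulated raw-scale means and
standard deviations hit their demographic targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "SnpSpec", "ExamSchedule", "EffectModel", "Pedigree",
    "simulate_pedigree", "simulate_genotypes", "simulate_phenotypes",
    "scenario_library", "lognormal_calibration", "default_effect_model",
    "DEFAULT_SNPS", "TC_TARGETS", "BIRTH_YEAR_PARAMS", "BASELINE_EXAM_YEAR",
]

SEXES = ("M", "W")
GENERATIONS = (1, 2, 3)

#: ln(10)/100 — derivative of the 100*log10 phenotype scale.
_C = math.log(10.0) / 100.0

#: Per-(sex, generation) targets for raw TC mean and SD in mg/dL.
TC_TARGETS: dict[tuple[str, int], tuple[float, float]] = {
    ("M", 1): (214.7, 38.8), ("W", 1): (210.7, 42.4),
    ("M", 2): (198.5, 38.4), ("W", 2): (190.5, 37.7),
    ("M", 3): (192.8, 37.0), ("W", 3): (185.3, 33.7),
}

#: Mean and SD of birth year per generation.
BIRTH_YEAR_PARAMS: dict[int, tuple[float, float]] = {
    1: (1911.0, 6.0), 2: (1937.0, 10.0), 3: (1963.0, 9.0)}

#: Calendar year of the baseline examination per generation.
BASELINE_EXAM_YEAR: dict[int, float] = {1: 1948.0, 2: 1971.0, 3: 2001.0}

#: Calendar year of DNA collection per generation (drives age at biospecimen).
BIOSPECIMEN_YEAR: dict[int, float] = {1: 1990.0, 2: 1998.0, 3: 2001.0}

#: The ten study SNPs with their minor-allele frequencies.
DEFAULT_SNPS: list["SnpSpec"]


@dataclass(frozen=True)
class SnpSpec:
    """A SNP identified by id with its minor-allele frequency."""

    snp_id: str
    maf: float

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise InputError(
                f"MAF for {self.snp_id} must be in (0, 0.5], got {self.maf}")


DEFAULT_SNPS = [
    SnpSpec("rs2479409", 0.34), SnpSpec("rs3177928", 0.14),
    SnpSpec("rs1800562", 0.06), SnpSpec("rs9488822", 0.37),
    SnpSpec("rs1564348", 0.16), SnpSpec("rs10128711", 0.23),
    SnpSpec("rs11220462", 0.13), SnpSpec("rs3764261", 0.30),
    SnpSpec("rs7206971", 0.49), SnpSpec("rs1800961", 0.03),
]


@dataclass(frozen=True)
class ExamSchedule:
    """Number and spacing (years) of examinations per generation.

    Defaults follow the emulated design: 16 biennial exams for the original
    generation, 7 quadrennial exams for the offspring, a single baseline
    exam for the third generation.
    """

    exams: dict[int, tuple[int, float]] = field(default_factory=lambda: {
        1: (16, 2.0), 2: (7, 4.0), 3: (1, 0.0)})

    def __post_init__(self):
        for gen, (n, _) in self.exams.items():
            if n < 1:
                raise InputError(f"generation {gen} must have >= 1 exam")

    def n_exams(self, generation: int) -> int:
        return self.exams[generation][0]

    def spacing(self, generation: int) -> float:
        return self.exams[generation][1]


@dataclass
class EffectModel:
    """Generative model for the transformed phenotype.

    ``intercept``, ``age_slope`` and ``reference_age`` are keyed by
    (sex, generation); ``beta`` by (snp_id, sex, generation, age_stratum)
    with stratum in {"younger", "older", "all"} on the 100*log10(mg/dL)
    scale per minor allele.  Variance components are on the same scale
    squared.  ``age_cutoffs`` map a generation to the biospecimen-age cutoff
    separating younger from older members; generations without a cutoff are
    a single "all" stratum.
    """

    intercept: dict[tuple[str, int], float]
    age_slope: dict[tuple[str, int], float]
    reference_age: dict[tuple[str, int], float]
    beta: dict[tuple[str, str, int, str], float] = field(default_factory=dict)
    sigma2_family: float = 0.0
    sigma2_subject: float = 0.0
    sigma2_residual: float = 0.0
    age_cutoffs: dict[int, float] = field(default_factory=dict)
    wga_effect: float = 0.0
    treatment_effect: float = 0.0
    fasting_effect: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_family", "sigma2_subject", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def beta_for(self, snp_id: str, sex: str, generation: int,
                 stratum: str) -> float:
        """Effect size for a cell; stratum-specific entries override 'all'."""
        b = self.beta.get((snp_id, sex, generation, stratum))
        if b is None:
            b = self.beta.get((snp_id, sex, generation, "all"), 0.0)
        return b

    def require_cell(self, sex: str, generation: int) -> None:
        if (sex, generation) not in self.intercept:
            raise ConfigurationError(
                f"effect model has no intercept for cell ({sex}, {generation})")


class Pedigree:
    """A validated three-generation pedigree.

    Wraps a DataFrame with one row per individual and columns
    ``individual_id, family_id, sex, generation, birth_year, father_id,
    mother_id, age_at_biospecimen``.  Parent ids are ``None``/NaN for
    founders (generation 1 and married-in spouses).
    """

    COLUMNS = ["individual_id", "family_id", "sex", "generation",
               "birth_year", "father_id", "mother_id", "age_at_biospecimen"]

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"pedigree missing columns: {missing}")
        ids = df["individual_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise InputError(f"duplicate individual id {dup!r}")
        gen = df.set_index("individual_id")["generation"]
        for col in ("father_id", "mother_id"):
            parents = df[col].dropna()
            unknown = parents[~parents.isin(ids)]
            if len(unknown):
                raise InputError(f"{col} {unknown.iloc[0]!r} not in pedigree")
            child_gen = df.loc[parents.index, "generation"]
            parent_gen = gen.loc[parents].to_numpy()
            if not np.all(parent_gen == child_gen.to_numpy() - 1):
                raise InputError(
                    "parent generation must be child generation - 1")

    @property
    def founders(self) -> pd.DataFrame:
        df = self.df
        return df[df["father_id"].isna() & df["mother_id"].isna()]


def _offspring_counts(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Resolve an offspring-per-couple distribution spec into counts.

    Accepts an int (constant), a ("poisson", lam, offset) tuple, or a
    callable ``f(rng, size) -> int array``.
    """
    if callable(spec):
        counts = np.asarray(spec(rng, size), dtype=int)
    elif isinstance(spec, int):
        counts = np.full(size, spec, dtype=int)
    elif isinstance(spec, (tuple, list)) and spec[0] == "poisson":
        lam = float(spec[1])
        offset = int(spec[2]) if len(spec) > 2 else 0
        counts = rng.poisson(lam, size) + offset
    else:
        raise InputError(f"unrecognised offspring spec {spec!r}")
    if (counts < 0).any():
        raise InputError("offspring counts must be non-negative")
    return counts


def _truncated_birth_years(rng, mean, sd, size):
    # Resample outside +/- 2 SD; keeps cohort enrollment windows realistic
    # and biospecimen ages inside the documented ranges.
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > 2 * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) > 2 * sd
    return np.round(out).astype(int)


def simulate_pedigree(
    n_families: int,
    offspring=("poisson", 2.0, 1),
    seed: int = 0,
    *,
    birth_year_params: dict[int, tuple[float, float]] | None = None,
    biospecimen_year: dict[int, float] | None = None,
    survival_thinning: float = 0.0,
) -> Pedigree:
    """Simulate extended families spanning three generations.

    Each family starts from a founder couple; each of their children
    (generation 2) marries a married-in founder spouse and has children
    (generation 3).  ``offspring`` sets the per-couple number-of-children
    distribution.  ``survival_thinning`` optionally removes that fraction of
    generation-1 members' biospecimen ages (they die before DNA collection),
    emulating survival selection; off by default.
    """
    if n_families < 1:
        raise InputError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    byp = birth_year_params or BIRTH_YEAR_PARAMS
    bsy = biospecimen_year or BIOSPECIMEN_YEAR

    rows: dict[str, list] = {c: [] for c in Pedigree.COLUMNS}

    def add(ids, fams, sexes, gens, bys, fathers, mothers):
        rows["individual_id"].extend(ids)
        rows["family_id"].extend(fams)
        rows["sex"].extend(sexes)
        rows["generation"].extend(gens)
        rows["birth_year"].extend(bys)
        rows["father_id"].extend(fathers)
        rows["mother_id"].extend(mothers)
        gens = np.asarray(gens)
        bys = np.asarray(bys, float)
        ages = np.array([bsy[g] for g in gens]) - bys
        rows["age_at_biospecimen"].extend(np.maximum(ages, 25.0))

    fam_ids = [f"F{i:04d}" for i in range(n_families)]

    # Generation 1: founder couples.
    g1_m = [f"{f}_G1M" for f in fam_ids]
    g1_w = [f"{f}_G1W" for f in fam_ids]
    by_m = _truncated_birth_years(rng, *byp[1], n_families)
    by_w = _truncated_birth_years(rng, *byp[1], n_families)
    add(g1_m, fam_ids, ["M"] * n_families, [1] * n_families, by_m,
        [None] * n_families, [None] * n_families)
    add(g1_w, fam_ids, ["W"] * n_families, [1] * n_families, by_w,
        [None] * n_families, [None] * n_families)

    # Generation 2: children of the founder couple, plus married-in spouses.
    n_child2 = _offspring_counts(offspring, rng, n_families)
    fam_of_child2 = np.repeat(np.arange(n_families), n_child2)
    n2 = len(fam_of_child2)
    within = np.concatenate([np.arange(k) for k in n_child2]) if n2 else np.array([], int)
    child2 = [f"{fam_ids[f]}_G2C{j}" for f, j in zip(fam_of_child2, within)]
    sex2 = np.where(rng.random(n2) < 0.5, "M", "W")
    by2 = _truncated_birth_years(rng, *byp[2], n2)
    add(child2, [fam_ids[f] for f in fam_of_child2], list(sex2),
        [2] * n2, by2, [g1_m[f] for f in fam_of_child2],
        [g1_w[f] for f in fam_of_child2])

    spouse2 = [f"{fam_ids[f]}_G2S{j}" for f, j in zip(fam_of_child2, within)]
    sex2s = np.where(sex2 == "M", "W", "M")
    by2s = _truncated_birth_years(rng, *byp[2], n2)
    add(spouse2, [fam_ids[f] for f in fam_of_child2], list(sex2s),
        [2] * n2, by2s, [None] * n2, [None] * n2)

    # Generation 3: children of each generation-2 couple.
    n_child3 = _offspring_counts(offspring, rng, n2)
    couple_of3 = np.repeat(np.arange(n2), n_child3)
    n3 = len(couple_of3)
    within3 = np.concatenate([np.arange(k) for k in n_child3]) if n3 else np.array([], int)
    child3 = [f"{child2[c]}_G3C{j}" for c, j in zip(couple_of3, within3)]
    sex3 = np.where(rng.random(n3) < 0.5, "M", "W")
    by3 = _truncated_birth_years(rng, *byp[3], n3)
    fathers3 = [child2[c] if sex2[c] == "M" else spouse2[c] for c in couple_of3]
    mothers3 = [spouse2[c] if sex2[c] == "M" else child2[c] for c in couple_of3]
    add(child3, [fam_ids[fam_of_child2[c]] for c in couple_of3], list(sex3),
        [3] * n3, by3, fathers3, mothers3)

    df = pd.DataFrame(rows)
    if survival_thinning > 0.0:
        g1 = df["generation"] == 1
        drop = g1 & (rng.random(len(df)) < survival_thinning)
        df.loc[drop, "age_at_biospecimen"] = np.nan
    return Pedigree(df)


def simulate_genotypes(pedigree: Pedigree, snps: list[SnpSpec],
                       seed: int = 0, *, missing_rate: float = 0.0
                       ) -> pd.DataFrame:
    """Minor-allele dosage matrix (individuals x SNPs).

    Founders are drawn in Hardy-Weinberg equilibrium at each SNP's MAF;
    descendants receive one allele from each parent with transmission
    probability dosage/2, so Mendelian consistency holds exactly.
    """
    rng = np.random.default_rng(seed)
    df = pedigree.df
    ids = df["individual_id"].to_numpy()
    idx = {i: k for k, i in enumerate(ids)}
    is_founder = (df["father_id"].isna() & df["mother_id"].isna()).to_numpy()
    n = len(df)

    geno = np.zeros((n, len(snps)))
    gens = df["generation"].to_numpy()
    father = df["father_id"].to_numpy()
    mother = df["mother_id"].to_numpy()
    # Per-generation index arrays let transmission be drawn vectorised.
    batches = []
    for gen in sorted(set(gens)):
        sel = np.flatnonzero((gens == gen) & ~is_founder)
        if len(sel):
            fi = np.array([idx[f] for f in father[sel]])
            mi = np.array([idx[m] for m in mother[sel]])
            batches.append((sel, fi, mi))
    for j, snp in enumerate(snps):
        if not 0.0 < snp.maf <= 0.5:  # re-validate: specs may be ad hoc dicts
            raise InputError(f"MAF out of (0, 0.5] for {snp.snp_id}")
        col = geno[:, j]
        col[is_founder] = rng.binomial(2, snp.maf, int(is_founder.sum()))
        for sel, fi, mi in batches:
            transmitted = (rng.random(len(sel)) < col[fi] / 2.0).astype(float)
            transmitted += rng.random(len(sel)) < col[mi] / 2.0
            col[sel] = transmitted
    out = pd.DataFrame(geno, index=pd.Index(ids, name="individual_id"),
                       columns=[s.snp_id for s in snps])
    if missing_rate > 0.0:
        mask = rng.random(out.shape) < missing_rate
        out = out.mask(mask)
    return out


def lognormal_calibration(mean_mgdl: float, sd_mgdl: float
                          ) -> tuple[float, float]:
    """Transformed-scale (mu, sigma) whose back-transform has the given
    raw-scale mean and SD (exact log-normal moment matching)."""
    if mean_mgdl <= 0 or sd_mgdl <= 0:
        raise InputError("mean and SD must be positive")
    cv2 = (sd_mgdl / mean_mgdl) ** 2
    sigma_t = math.sqrt(math.log1p(cv2)) / _C
    mu_t = (math.log(mean_mgdl) - (sigma_t * _C) ** 2 / 2.0) / _C
    return mu_t, sigma_t


def default_effect_model(
    beta: dict[tuple[str, str, int, str], float] | None = None,
    *,
    variance_shares: tuple[float, float, float] = (0.15, 0.50, 0.35),
    age_slope: float = 0.22,
    age_cutoffs: dict[int, float] | None = None,
) -> EffectModel:
    """Effect model calibrated to the per-cell TC means/SDs in ``TC_TARGETS``.

    ``variance_shares`` splits the calibrated transformed-scale variance
    into (family, subject, residual) components; the default puts about
    two-thirds of the variance between subjects, reflecting the strong
    within-person tracking of cholesterol.  ``age_slope`` is in transformed
    units per year (0.22 corresponds to roughly +1 mg/dL per year at
    typical TC levels).
    """
    if abs(sum(variance_shares) - 1.0) > 1e-9:
        raise ConfigurationError("variance shares must sum to 1")
    intercepts, slopes, ref_ages = {}, {}, {}
    sigma2 = []
    for (sex, gen), (m, sd) in TC_TARGETS.items():
        mu_t, sigma_t = lognormal_calibration(m, sd)
        intercepts[(sex, gen)] = mu_t
        slopes[(sex, gen)] = age_slope
        ref_ages[(sex, gen)] = (
            BASELINE_EXAM_YEAR[gen] - BIRTH_YEAR_PARAMS[gen][0])
        sigma2.append(sigma_t ** 2)
    total = float(np.mean(sigma2))
    sf, ss, sr = variance_shares
    return EffectModel(
        intercept=intercepts, age_slope=slopes, reference_age=ref_ages,
        beta=dict(beta or {}),
        sigma2_family=sf * total, sigma2_subject=ss * total,
        sigma2_residual=sr * total,
        age_cutoffs={2: 60.0, 3: 40.0} if age_cutoffs is None else age_cutoffs,
    )


#: Per-generation probability that an exam record is a 12h+ fast.
FASTING_PREVALENCE = {1: 0.10, 2: 0.90, 3: 0.95}
#: Per-generation probability of lipid-lowering treatment at an exam.
TREATMENT_PREVALENCE = {1: 0.02, 2: 0.08, 3: 0.15}
#: Probability a DNA sample was whole-genome amplified.
WGA_PREVALENCE = 0.10
#: Probability fasting hours are unrecorded.
UNKNOWN_FASTING_RATE = 0.05


def _stratum_of(ages: np.ndarray, gens: np.ndarray,
                cutoffs: dict[int, float]) -> np.ndarray:
    out = np.full(len(ages), "all", dtype=object)
    for gen, cut in cutoffs.items():
        sel = (gens == gen) & ~np.isnan(ages)
        out[sel & (ages < cut)] = "younger"
        out[sel & (ages >= cut)] = "older"
    return out


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    model: EffectModel,
    schedule: ExamSchedule | None = None,
    seed: int = 0,
    *,
    missing_rate: float = 0.0,
    fasting_prevalence: dict[int, float] | None = None,
    treatment_prevalence: dict[int, float] | None = None,
    wga_prevalence: float = WGA_PREVALENCE,
) -> pd.DataFrame:
    """Long-format repeated TC measurements for a simulated cohort.

    One row per individual x exam with columns ``individual_id, family_id,
    sex, generation, exam_index, age_at_exam, tc_mgdl, fasting_hours,
    lipid_treatment, wga``.  The transformed phenotype is the sum of the
    cell intercept, the age trend, all SNP dosage effects, the shared family
    and subject intercepts and a per-record residual; records of one person
    share the subject and family draws.  ``missing_rate`` removes exam
    records completely at random.
    """
    schedule = schedule or ExamSchedule()
    rng = np.random.default_rng(seed)
    ped = pedigree.df
    sexes = ped["sex"].to_numpy()
    gens = ped["generation"].to_numpy()
    for sex, gen in {(s, g) for s, g in zip(sexes, gens)}:
        model.require_cell(sex, gen)

    n = len(ped)
    fam_labels, fam_codes = np.unique(ped["family_id"].to_numpy(),
                                      return_inverse=True)
    fam_eff = (math.sqrt(model.sigma2_family)
               * rng.standard_normal(len(fam_labels)))[fam_codes]
    subj_eff = math.sqrt(model.sigma2_subject) * rng.standard_normal(n)
    wga = rng.random(n) < wga_prevalence

    strata = _stratum_of(ped["age_at_biospecimen"].to_numpy(float), gens,
                         model.age_cutoffs)
    # Static genetic contribution per individual (sum over SNPs).
    dosages = genotypes.reindex(ped["individual_id"]).to_numpy()
    snp_ids = list(genotypes.columns)
    gsum = np.zeros(n)
    for j, snp in enumerate(snp_ids):
        b = np.array([model.beta_for(snp, s, g, st)
                      for s, g, st in zip(sexes, gens, strata)])
        gsum += b * np.nan_to_num(dosages[:, j])

    intercept = np.array([model.intercept[(s, g)] for s, g in zip(sexes, gens)])
    slope = np.array([model.age_slope[(s, g)] for s, g in zip(sexes, gens)])
    ref_age = np.array([model.reference_age[(s, g)]
                        for s, g in zip(sexes, gens)])
    static = intercept + gsum + fam_eff + subj_eff + model.wga_effect * wga

    fprev = fasting_prevalence or FASTING_PREVALENCE
    tprev = treatment_prevalence or TREATMENT_PREVALENCE

    frames = []
    for gen in sorted(set(gens)):
        sel = np.flatnonzero(gens == gen)
        n_ex = schedule.n_exams(gen)
        spacing = schedule.spacing(gen)
        base_age = (BASELINE_EXAM_YEAR[gen]
                    - ped["birth_year"].to_numpy(float)[sel])
        rows = np.repeat(sel, n_ex)
        exam = np.tile(np.arange(1, n_ex + 1), len(sel))
        age = base_age[np.repeat(np.arange(len(sel)), n_ex)] \
            + (exam - 1) * spacing
        m = len(rows)
        treat = rng.random(m) < tprev.get(gen, 0.0)
        fast = rng.random(m) < fprev.get(gen, 0.0)
        hours = np.where(fast, rng.uniform(12.0, 16.0, m),
                         rng.uniform(0.0, 8.0, m))
        hours[rng.random(m) < UNKNOWN_FASTING_RATE] = np.nan
        t = (static[rows] + slope[rows] * (age - ref_age[rows])
             + model.treatment_effect * treat
             + model.fasting_effect * fast
             + math.sqrt(model.sigma2_residual) * rng.standard_normal(m))
        frames.append(pd.DataFrame({
            "individual_id": ped["individual_id"].to_numpy()[rows],
            "family_id": ped["family_id"].to_numpy()[rows],
            "sex": sexes[rows], "generation": gens[rows],
            "exam_index": exam, "age_at_exam": age,
            "tc_mgdl": np.power(10.0, t / 100.0),
            "fasting_hours": hours, "lipid_treatment": treat, "wga": wga[rows],
        }))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["family_id", "individual_id", "exam_index"],
                          kind="stable", ignore_index=True)
    if missing_rate > 0.0:
        out = out[rng.random(len(out)) >= missing_rate].reset_index(drop=True)
    return out


def scenario_library(name: str, *, beta: float = 2.0,
                     snps: list[SnpSpec] | None = None) -> EffectModel:
    """Named effect-size profiles over the sex x generation x age-stratum grid.

    - ``homogeneous``: the same effect in every cell (``beta=0`` gives a
      null model);
    - ``generation_clustered``: effects confined to the youngest generation;
    - ``antagonistic``: the younger stratum of generation 3 carries the
      opposite-signed effect of every other cell, so pooled effects cancel;
    - ``age_stratum``: effects confined to the younger strata of the two
      generations that have an age cutoff.

    ``beta`` is on the transformed scale (100*log10 mg/dL per minor allele)
    and is applied to every SNP in ``snps`` (default: the ten study SNPs).
    """
    snps = snps if snps is not None else DEFAULT_SNPS
    betas: dict[tuple[str, str, int, str], float] = {}
    if name == "homogeneous":
        for s in snps:
            for sex in SEXES:
                for gen in GENERATIONS:
                    betas[(s.snp_id, sex, gen, "all")] = beta
    elif name == "generation_clustered":
        for s in snps:
            for sex in SEXES:
                betas[(s.snp_id, sex, 3, "all")] = beta
    elif name == "antagonistic":
        for s in snps:
            for sex in SEXES:
                betas[(s.snp_id, sex, 1, "all")] = beta
                betas[(s.snp_id, sex, 2, "all")] = beta
                betas[(s.snp_id, sex, 3, "older")] = beta
                betas[(s.snp_id, sex, 3, "younger")] = -beta
    elif name == "age_stratum":
        for s in snps:
            for sex in SEXES:
                for gen in (2, 3):
                    betas[(s.snp_id, sex, gen, "younger")] = beta
                    betas[(s.snp_id, sex, gen, "older")] = 0.0
    else:
        raise LookupError(f"unknown scenario {name!r}")
    return default_effect_model(betas)
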