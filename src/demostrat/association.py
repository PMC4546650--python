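"""Additive-genotype association models for repeated lipid measurements.

Total cholesterol is analysed either raw (mg/dL) or, by default, as
100*log10(TC) — the log transform corrects the right skew of raw TC and the
factor of 100 keeps effect sizes on a convenient scale.  Associations use
the additive genetic model: the phenotype is regressed on the minor-allele
dosage (0/1/2), adjusting for requested covariates.

Two model levels are provided.  The *baseline* (two-level) model uses one
record per person — the baseline examination — with a random intercept per
family to absorb familial correlation.  The *cumulative* (three-level)
model uses every examination record, adding a subject-within-family random
intercept for the repeated measurements; its fixed-effect estimate is the
cumulative genetic effect over follow-up, and the extra records typically
buy a smaller standard error than the baseline fit.

Estimation is by REML; p-values are two-sided Wald tests against the normal
reference.  Individuals with a missing dosage for the SNP under test are
dropped from that fit (complete case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegeneratePredictorError, InputError
from .lmm import fit_nested_lmm

__all__ = [
    "AssocResult", "transform_tc", "dichotomize_fasting",
    "fit_additive_baseline", "fit_additive_cumulative",
    "fit_additive_batch", "covariate_effect_test", "DEFAULT_COVARIATES",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "wga", "sex", "generation")

RESULT_COLUMNS = ["snp_id", "cell", "n_individuals", "n_records",
                  "beta", "se", "p_value", "model_level", "scale"]


@dataclass
class AssocResult:
    """Effect of one predictor (SNP dosage or a flag) in one cell."""

    snp_id: str
    cell: str
    n_individuals: int
    n_records: int
    beta: float
    se: float
    p_value: float
    model_level: str            # "two_level" | "three_level"
    scale: str                  # "raw" | "transformed"

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in RESULT_COLUMNS}

    @property
    def z(self) -> float:
        return self.beta / self.se


def transform_tc(tc_mgdl):
    """100*log10(TC); strictly increasing, defined for positive TC only."""
    arr = np.asarray(tc_mgdl, dtype=float)
    if np.any(arr <= 0):
        raise InputError("TC must be positive (mg/dL)")
    out = 100.0 * np.log10(arr)
    return out if out.ndim else float(out)


def dichotomize_fasting(fasting_hours):
    """True (fasting) for 12+ hours of fasting or unknown fasting status,
    False for a recorded fast shorter than 12 hours."""
    arr = np.asarray(fasting_hours, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise InputError("fasting hours cannot be negative")
    out = np.isnan(arr) | (arr >= 12.0)
    return out if out.ndim else bool(out)


def _baseline_records(pheno: pd.DataFrame, exam: int | None) -> pd.DataFrame:
    if exam is not None:
        return pheno[pheno["exam_index"] == exam]
    first = pheno.groupby("individual_id")["exam_index"].transform("min")
    return pheno[pheno["exam_index"] == first]


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (family, individual, exam) via integer codes.

    Equivalent to ``sort_values`` on the three columns but much cheaper on
    repeated string keys; makes every fit independent of input row order.
    """
    fam = pd.factorize(df["family_id"], sort=True)[0]
    ind = pd.factorize(df["individual_id"], sort=True)[0]
    order = np.lexsort((df["exam_index"].to_numpy(), ind, fam))
    if np.array_equal(order, np.arange(len(df))):
        return df
    return df.take(order)


def _covariate_columns(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate block; constant columns are dropped with a log line
    (e.g. sex within a single-sex cell, cohort within one generation)."""
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            cols.append(df["age_at_exam"].to_numpy(float)); names.append("age")
        elif cov == "sex":
            cols.append((df["sex"].to_numpy() == "W").astype(float))
            names.append("sex_W")
        elif cov == "generation":
            gens = sorted(df["generation"].unique())
            for g in gens[1:]:
                cols.append((df["generation"].to_numpy() == g).astype(float))
                names.append(f"gen_{g}")
        elif cov == "wga":
            cols.append(df["wga"].to_numpy(float)); names.append("wga")
        elif cov == "treatment":
            cols.append(df["lipid_treatment"].to_numpy(float))
            names.append("treatment")
        elif cov == "fasting":
            cols.append(dichotomize_fasting(
                df["fasting_hours"].to_numpy()).astype(float))
            names.append("fasting")
        elif cov in df.columns:
            cols.append(df[cov].to_numpy(float)); names.append(cov)
        else:
            raise InputError(f"unknown covariate {cov!r}")
    keep_cols, keep_names = [], []
    for c, nm in zip(cols, names):
        if np.ptp(c) == 0.0:
            logger.debug("covariate %s constant in this cell; dropped", nm)
            continue
        keep_cols.append(c); keep_names.append(nm)
    block = (np.column_stack(keep_cols) if keep_cols
             else np.empty((len(df), 0)))
    return block, keep_names


def _fit(df: pd.DataFrame, effect: np.ndarray, effect_name: str,
         covariates, scale: str, model_level: str, cell: str) -> AssocResult:
    if scale not in ("raw", "transformed"):
        raise InputError(f"unknown scale {scale!r}")
    y = (transform_tc(df["tc_mgdl"].to_numpy())
         if scale == "transformed" else df["tc_mgdl"].to_numpy(float))
    if np.ptp(effect) == 0.0:
        raise DegeneratePredictorError(
            f"{effect_name} is constant in this sample")
    cov_block, cov_names = _covariate_columns(df, covariates)
    X = np.column_stack([np.ones(len(df)), effect, cov_block])
    names = ["const", effect_name] + cov_names
    fams = df["family_id"].to_numpy()
    if len(np.unique(fams)) < 2:
        raise InputError("need at least 2 families")
    subject = (df["individual_id"].to_numpy()
               if model_level == "three_level" else None)
    res = fit_nested_lmm(X, y, fams, subject, names=names)
    beta, se, p = res[effect_name]
    return AssocResult(
        snp_id=effect_name, cell=cell,
        n_individuals=int(df["individual_id"].nunique()),
        n_records=int(len(df)), beta=beta, se=se, p_value=p,
        model_level=model_level, scale=scale)


def _fit_one(pheno, geno, snp_id, covariates, scale, model_level, exam, cell):
    _, res = next(iter(fit_additive_batch(
        pheno, geno, [snp_id], covariates=covariates, scale=scale,
        model_level=model_level, exam=exam, cell=cell)))
    if isinstance(res, Exception):
        raise res
    return res


def fit_additive_baseline(
    pheno: pd.DataFrame, geno: pd.DataFrame, snp_id: str,
    covariates=DEFAULT_COVARIATES, scale: str = "transformed",
    *, exam: int | None = None, cell: str = "pooled",
) -> AssocResult:
    """Two-level (family random intercept) additive fit at baseline.

    Uses each individual's first available examination record (or the exam
    given explicitly).  ``covariates`` may include "age", "sex",
    "generation", "wga", "treatment", "fasting" or any numeric phenotype
    column; covariates constant within the sample are dropped.
    """
    return _fit_one(pheno, geno, snp_id, covariates, scale, "two_level",
                    exam, cell)


def fit_additive_cumulative(
    pheno: pd.DataFrame, geno: pd.DataFrame, snp_id: str,
    covariates=DEFAULT_COVARIATES, scale: str = "transformed",
    *, cell: str = "pooled",
) -> AssocResult:
    """Three-level (family + subject) additive fit over all examinations.

    The age covariate is the per-record age at examination, so the repeated
    measurements contribute longitudinal information; the estimate is the
    cumulative genetic effect over follow-up.
    """
    return _fit_one(pheno, geno, snp_id, covariates, scale, "three_level",
                    None, cell)


def fit_additive_batch(
    pheno: pd.DataFrame, geno: pd.DataFrame, snp_ids,
    covariates=DEFAULT_COVARIATES, scale: str = "transformed",
    model_level: str = "two_level", *, exam: int | None = None,
    cell: str = "pooled",
):
    """Fit several SNPs against one prepared sample.

    The phenotype rows, response and covariate block are prepared once and
    reused across SNPs; each SNP still gets its own complete-case restriction
    (rows with a missing dosage for that SNP are masked out).  Results are
    numerically identical to the corresponding single-SNP calls — the scan
    machinery relies on this.  Yields ``(snp_id, AssocResult | Exception)``
    pairs.
    """
    if scale not in ("raw", "transformed"):
        raise InputError(f"unknown scale {scale!r}")
    if model_level not in ("two_level", "three_level"):
        raise InputError(f"unknown model level {model_level!r}")
    df = pheno if model_level == "three_level" else _baseline_records(pheno, exam)
    n0 = len(df)
    df = df.dropna(subset=["tc_mgdl", "age_at_exam"]
                   if "age" in covariates else ["tc_mgdl"])
    if len(df) < n0:
        logger.info("dropped %d records with missing phenotype/age",
                    n0 - len(df))
    if len(df) == 0:
        raise InputError("no usable records")
    df = _canonical_sort(df)
    y_all = (transform_tc(df["tc_mgdl"].to_numpy())
             if scale == "transformed" else df["tc_mgdl"].to_numpy(float))
    cov_all, cov_names = _covariate_columns(df, covariates)
    fams_all = df["family_id"].to_numpy()
    subj_all = df["individual_id"].to_numpy()
    n_ind_all = df["individual_id"].nunique()
    dosages = geno.reindex(df["individual_id"]).to_numpy()
    col_of = {s: k for k, s in enumerate(geno.columns)}

    for snp_id in snp_ids:
        try:
            if snp_id not in col_of:
                raise InputError(f"SNP {snp_id!r} not in genotype matrix")
            d = dosages[:, col_of[snp_id]]
            mask = ~np.isnan(d)
            complete = mask.all()
            if complete:
                d_, y_, cov_, names_ = d, y_all, cov_all, cov_names
            else:
                logger.info("%s: dropped %d records with missing dosage",
                            snp_id, int((~mask).sum()))
                d_, y_ = d[mask], y_all[mask]
                cov_, names_ = cov_all[mask], cov_names
                if cov_.shape[1]:
                    keep = np.ptp(cov_, axis=0) != 0.0
                    if not keep.all():
                        # complete-case masking collapsed a covariate
                        cov_ = cov_[:, keep]
                        names_ = [nm for nm, k in zip(names_, keep) if k]
            fams = fams_all if complete else fams_all[mask]
            if np.ptp(d_) == 0.0:
                raise DegeneratePredictorError(
                    f"{snp_id} is constant in this sample")
            if len(np.unique(fams)) < 2:
                raise InputError("need at least 2 families")
            X = np.column_stack([np.ones(len(d_)), d_, cov_])
            subject = ((subj_all if complete else subj_all[mask])
                       if model_level == "three_level" else None)
            res = fit_nested_lmm(X, y_, fams, subject,
                                 names=["const", snp_id] + names_)
            beta, se, p = res[snp_id]
            n_ind = n_ind_all if complete else \
                int(pd.unique(subj_all[mask]).size)
            yield snp_id, AssocResult(
                snp_id=snp_id, cell=cell, n_individuals=n_ind,
                n_records=int(len(d_)), beta=beta, se=se, p_value=p,
                model_level=model_level, scale=scale)
        except (InputError, RuntimeError) as exc:
            yield snp_id, exc


def covariate_effect_test(
    pheno: pd.DataFrame, covariate: str,
    covariates=("age", "sex"), scale: str = "transformed",
    *, exam: int | None = None, cell: str = "pooled",
) -> AssocResult:
    """Association of TC with a binary flag at one examination.

    Used for the fasting and lipid-lowering-treatment sensitivity screens:
    a two-level model with the flag as the effect of interest.  The flag
    must take both values in the sample.
    """
    df = _baseline_records(pheno, exam)
    df = df.dropna(subset=["tc_mgdl"])
    df = _canonical_sort(df)
    if covariate == "fasting":
        flag = dichotomize_fasting(df["fasting_hours"].to_numpy()).astype(float)
    elif covariate == "treatment":
        flag = df["lipid_treatment"].to_numpy(float)
    elif covariate in df.columns:
        flag = df[covariate].to_numpy(float)
    else:
        raise InputError(f"unknown covariate {covariate!r}")
    if np.ptp(flag) == 0.0:
        raise DegeneratePredictorError(
            f"covariate {covariate!r} has a single level")
    return _fit(df, flag, covariate, covariates, scale, "two_level", cell)
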