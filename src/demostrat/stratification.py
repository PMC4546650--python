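"""Demographic cells and the SNP x cell association scan.

The scan re-estimates each SNP's additive effect separately inside
demographic cells — sex x generation by default, optionally split further
into younger/older birth-cohort strata by age at biospecimen collection —
and labels every estimate as significant (p <= 0.05), suggestive
(0.05 < p <= 0.1) or null.  Cells are a partition: each genotyped
individual belongs to exactly one cell for a given stratification.

Cross-generation comparisons at matched ages are supported by ranking one
cohort's examinations by the distance between their mean age at measurement
and a target cohort's mean age, so a younger generation measured once can
be compared against the examination of an older generation taken at the
same mean age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssocResult, fit_additive_batch
from .exceptions import InputError

__all__ = ["DemographicCell", "CellScan", "build_cells",
           "split_by_median_age", "match_age_cohorts", "scan",
           "classify_p", "SIGNIFICANT_P", "SUGGESTIVE_P"]

logger = logging.getLogger(__name__)

SIGNIFICANT_P = 0.05
SUGGESTIVE_P = 0.10


@dataclass
class DemographicCell:
    """A set of individuals sharing sex / generation / age-stratum labels."""

    sex: str                    # "M", "W" or "both"
    generation: object          # 1, 2, 3 or "pooled"
    age_stratum: str = "all"    # "younger", "older" or "all"
    member_ids: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.sex}/gen{self.generation}/{self.age_stratum}"

    def __len__(self) -> int:
        return len(self.member_ids)


def classify_p(p: float, significant: float = SIGNIFICANT_P,
               suggestive: float = SUGGESTIVE_P) -> str:
    """Significance class from the p-value alone."""
    if p <= significant:
        return "significant"
    if p <= suggestive:
        return "suggestive"
    return "null"


@dataclass
class CellScan:
    """Per-(SNP, cell) association results with significance classes."""

    results: list                  # (AssocResult, class) pairs
    errors: list = field(default_factory=list)   # (snp, cell_label, message)
    significant_p: float = SIGNIFICANT_P
    suggestive_p: float = SUGGESTIVE_P

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res, cls in self.results:
            d = res.to_dict()
            d["class"] = cls
            rows.append(d)
        return pd.DataFrame(rows)

    @property
    def n_tests(self) -> int:
        return len(self.results)

    def count(self, cls: str) -> int:
        return sum(1 for _, c in self.results if c == cls)

    @property
    def n_significant(self) -> int:
        return self.count("significant")

    @property
    def n_suggestive(self) -> int:
        return self.count("suggestive")


def build_cells(individuals: pd.DataFrame, axes=("sex", "generation")
                ) -> list[DemographicCell]:
    """Partition individuals into demographic cells along the given axes.

    ``individuals`` needs one row per person with ``individual_id`` plus a
    column per axis; sex x generation over three generations yields the six
    scan cells.  Empty combinations are retained (with no members) so scans
    can report them as skipped.
    """
    axes = list(axes)
    if not axes:
        raise InputError("axes must be non-empty")
    for ax in axes:
        if ax not in ("sex", "generation"):
            raise InputError(f"unknown stratification axis {ax!r}")
    sex_levels = sorted(individuals["sex"].unique()) if "sex" in axes else ["both"]
    gen_levels = (sorted(individuals["generation"].unique())
                  if "generation" in axes else ["pooled"])
    cells = []
    for sex in sex_levels:
        for gen in gen_levels:
            mask = np.ones(len(individuals), bool)
            if "sex" in axes:
                mask &= (individuals["sex"] == sex).to_numpy()
            if "generation" in axes:
                mask &= (individuals["generation"] == gen).to_numpy()
            cells.append(DemographicCell(
                sex=sex, generation=gen,
                member_ids=list(individuals.loc[mask, "individual_id"])))
    return cells


def split_by_median_age(cell: DemographicCell, cutoff_years: float,
                        ages: pd.Series
                        ) -> tuple[DemographicCell, DemographicCell]:
    """Split a cell at an age-at-biospecimen cutoff.

    Members with age below the cutoff form the younger stratum; the cutoff
    itself belongs to the older stratum.  Members with unknown age are
    excluded from both strata (and counted in a log line).
    """
    a = ages.reindex(cell.member_ids)
    known = a.dropna()
    if known.empty:
        raise InputError("no member has a known age at biospecimen")
    n_unknown = len(a) - len(known)
    if n_unknown:
        logger.info("split_by_median_age: %d members lack an age and were "
                    "excluded", n_unknown)
    younger = DemographicCell(cell.sex, cell.generation, "younger",
                              list(known.index[known < cutoff_years]))
    older = DemographicCell(cell.sex, cell.generation, "older",
                            list(known.index[known >= cutoff_years]))
    return younger, older


@dataclass
class AgeMatch:
    """Ranked examination candidates for an age-matched comparison."""

    target_mean_age: float
    candidates: pd.DataFrame     # exam_index, mean_age, abs_diff (ranked)
    selected_exam: int | None


def match_age_cohorts(target_pheno: pd.DataFrame,
                      candidate_pheno: pd.DataFrame,
                      *, select_exam: int | None = None,
                      window_years: float = 2.0) -> AgeMatch:
    """Rank a cohort's examinations by closeness of mean age at measurement
    to another cohort's mean age.

    Matching is on examination-level mean ages, not on individuals.  The
    default selection is the top-ranked exam; pass ``select_exam`` to
    override with any listed candidate (substantive grounds may favour a
    slightly more distant exam).  Ties rank the lower exam index first.
    """
    if candidate_pheno.empty:
        raise InputError("candidate cohort has no records")
    target = float(target_pheno["age_at_exam"].mean())
    means = (candidate_pheno.groupby("exam_index")["age_at_exam"]
             .mean().rename("mean_age").reset_index())
    means["abs_diff"] = (means["mean_age"] - target).abs()
    means = means.sort_values(["abs_diff", "exam_index"], kind="stable",
                              ignore_index=True)
    in_window = means[means["abs_diff"] <= window_years]
    if in_window.empty:
        logger.warning("no examination within %.1f years of target mean age "
                       "%.1f", window_years, target)
    selected = (int(select_exam) if select_exam is not None
                else int(means.loc[0, "exam_index"]))
    if select_exam is not None and \
            select_exam not in set(means["exam_index"]):
        raise InputError(f"exam {select_exam} not among candidates")
    return AgeMatch(target, means, selected)


def scan(pheno: pd.DataFrame, geno: pd.DataFrame, snps,
         cells: list[DemographicCell], model: str = "baseline",
         covariates=("age", "wga"), scale: str = "transformed",
         *, significant_p: float = SIGNIFICANT_P,
         suggestive_p: float = SUGGESTIVE_P) -> CellScan:
    """Fit every SNP in every cell and attach significance classes.

    Each (SNP, cell) entry is an independent fit restricted to the cell's
    members; fit failures (degenerate dosage, too few families) are
    recorded in ``errors`` and the scan continues.  ``snps`` may be SNP ids
    or SnpSpec objects.
    """
    if model not in ("baseline", "cumulative"):
        raise InputError(f"unknown scan model {model!r}")
    snp_ids = [getattr(s, "snp_id", s) for s in snps]
    level = "two_level" if model == "baseline" else "three_level"
    entries: dict[tuple[str, str], object] = {}
    errors = []
    for cell in cells:
        if len(cell) == 0:
            logger.warning("cell %s is empty; skipped", cell.label)
            errors.extend((s, cell.label, "empty cell") for s in snp_ids)
            continue
        sub = pheno[pheno["individual_id"].isin(cell.member_ids)]
        for snp_id, res in fit_additive_batch(
                sub, geno, snp_ids, covariates=covariates, scale=scale,
                model_level=level, cell=cell.label):
            if isinstance(res, Exception):
                errors.append((snp_id, cell.label, str(res)))
            else:
                entries[(snp_id, cell.label)] = res
    # Report in SNP-major order regardless of the cell-major fit order.
    results = [(entries[(s, c.label)],
                classify_p(entries[(s, c.label)].p_value,
                           significant_p, suggestive_p))
               for s in snp_ids for c in cells
               if (s, c.label) in entries]
    return CellScan(results, errors, significant_p, suggestive_p)
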