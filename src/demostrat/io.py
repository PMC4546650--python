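"""Readers and writers for pedigrees, genotype dosages and phenotypes.

Canonical tabular dialect: UTF-8, tab-separated, '.' decimal point, 'NA'
for missing; writers stamp the generating seed in a '#' header comment and
readers skip '#' lines.  Pedigrees use the PLINK-FAM six-column layout
(family, individual, father, mother, sex 1/2, phenotype placeholder) with
'0' for an absent parent; generations are reconstructed from parent links
when reading (married-in spouses take their partner's generation).
Genotypes are a dosage matrix (individuals x SNPs, entries 0/1/2 or NA),
optionally readable from a VCF where dosages derive from GT fields.
"""

from __future__ import annotations

import hashlib

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError, ParseError
from .synthetic import Pedigree

__all__ = [
    "RunConfig", "read_pedigree", "write_pedigree",
    "read_genotypes", "write_genotypes", "read_genotypes_vcf",
    "read_phenotypes", "write_phenotypes",
]

PHENO_COLUMNS = ["individual_id", "family_id", "sex", "generation",
                 "exam_index", "age_at_exam", "tc_mgdl", "fasting_hours",
                 "lipid_treatment", "wga"]


def _seed_header(seed) -> str:
    return f"# demostrat seed={seed}\n" if seed is not None else ""


def write_pedigree(path, pedigree: Pedigree, seed=None) -> None:
    """PLINK-FAM-style whitespace-delimited pedigree file."""
    df = pedigree.df
    sex_code = df["sex"].map({"M": 1, "W": 2})
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        for fam, ind, fa, mo, sx in zip(
                df["family_id"], df["individual_id"],
                df["father_id"], df["mother_id"], sex_code):
            fa = fa if isinstance(fa, str) else "0"
            mo = mo if isinstance(mo, str) else "0"
            fh.write(f"{fam}\t{ind}\t{fa}\t{mo}\t{sx}\t-9\n")


def _infer_generations(ids, fathers, mothers) -> np.ndarray:
    """Generation = 1 + max parental generation; spouses (founders whose
    children have a non-founder co-parent) inherit the partner's level."""
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    gen = np.where([f is None and m is None
                    for f, m in zip(fathers, mothers)], 1, 0)
    # Resolve children by repeated passes; lack of progress means a cycle.
    while (gen == 0).any():
        progressed = False
        for k in range(n):
            if gen[k]:
                continue
            fg = gen[index[fathers[k]]]
            mg = gen[index[mothers[k]]]
            if fg and mg:
                gen[k] = max(fg, mg) + 1
                progressed = True
        if not progressed:
            bad = ids[int(np.flatnonzero(gen == 0)[0])]
            raise ParseError(f"cyclic parentage involving {bad!r}")
    # Couples: both parents of any child sit at the same level.
    changed = True
    while changed:
        changed = False
        for k in range(n):
            if fathers[k] is None:
                continue
            fi, mi = index[fathers[k]], index[mothers[k]]
            level = max(gen[fi], gen[mi])
            if gen[fi] != level or gen[mi] != level:
                gen[fi] = gen[mi] = level
                changed = True
            if gen[k] != level + 1:
                gen[k] = level + 1
                changed = True
    return gen


def read_pedigree(path) -> Pedigree:
    """Parse a PLINK-FAM-style file into a validated pedigree.

    Row order is free (children may precede parents).  Errors carry the
    offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError("expected >= 5 whitespace-separated fields",
                                 lineno)
            fam, ind, fa, mo, sx = parts[:5]
            if sx not in ("1", "2"):
                raise ParseError(f"sex code must be 1 or 2, got {sx!r}",
                                 lineno)
            rows.append((lineno, fam, ind,
                         None if fa == "0" else fa,
                         None if mo == "0" else mo,
                         "M" if sx == "1" else "W"))
    if not rows:
        raise ParseError("empty pedigree file")
    seen = {}
    for lineno, _, ind, *_ in rows:
        if ind in seen:
            raise ParseError(f"duplicate individual id {ind!r}", lineno)
        seen[ind] = lineno
    ids = np.array([r[2] for r in rows], dtype=object)
    fathers = [r[3] for r in rows]
    mothers = [r[4] for r in rows]
    for lineno, _, _, fa, mo, _ in rows:
        for parent in (fa, mo):
            if parent is not None and parent not in seen:
                raise ParseError(f"unknown parent reference {parent!r}",
                                 lineno)
    gens = _infer_generations(ids, fathers, mothers)
    df = pd.DataFrame({
        "individual_id": ids,
        "family_id": [r[1] for r in rows],
        "sex": [r[5] for r in rows],
        "generation": gens,
        "birth_year": np.nan,
        "father_id": fathers,
        "mother_id": mothers,
        "age_at_biospecimen": np.nan,
    })
    return Pedigree(df)


def write_genotypes(path, genotypes: pd.DataFrame, seed=None) -> None:
    """Tab-separated dosage matrix, individuals as rows."""
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        genotypes.to_csv(fh, sep="\t", na_rep="NA",
                         index_label="individual_id")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="individual_id")
    arr = df.to_numpy(float)
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ParseError(
            f"dosage {arr[i, j]!r} for {df.index[i]} x {df.columns[j]} "
            "is outside {0, 1, 2}")
    return df.astype(float)


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Dosage matrix from a VCF: ALT-allele counts from GT, './.' -> NA."""
    from cyvcf2 import VCF     # optional dependency, imported lazily
    vcf = VCF(path)
    samples = list(vcf.samples)
    data, snp_ids = [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                           default=np.nan)
        data.append(dosage)
    return pd.DataFrame(np.array(data).T,
                        index=pd.Index(samples, name="individual_id"),
                        columns=snp_ids)


def write_phenotypes(path, pheno: pd.DataFrame, seed=None) -> None:
    """Long-format phenotype TSV, one row per individual x exam."""
    with open(path, "w") as fh:
        fh.write(_seed_header(seed))
        pheno.to_csv(fh, sep="\t", na_rep="NA", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, na_values=["NA"])
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype table missing columns: {missing}")
    if not np.issubdtype(df["tc_mgdl"].dtype, np.number):
        raise ParseError("non-numeric TC value")
    if (df["tc_mgdl"] <= 0).any():
        bad = df.index[df["tc_mgdl"] <= 0][0]
        raise ParseError(f"non-positive TC at row {bad}")
    for col in ("lipid_treatment", "wga"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        df[col] = df[col].astype(bool)
    return df


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    seed: int = 0
    scenario: str = "generation_clustered"
    beta: float = 2.0
    n_families: int = 250
    thresholds: dict = field(default_factory=lambda:
                             {"significant": 0.05, "suggestive": 0.1})
    age_cutoffs: dict = field(default_factory=lambda: {2: 60.0, 3: 40.0})
    alpha: float = 0.05
    power: float = 0.80
    outdir: str = "demostrat_run"

    def __post_init__(self):
        if not self.thresholds["significant"] < self.thresholds["suggestive"]:
            raise ConfigurationError(
                "significant threshold must be below suggestive threshold")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "age_cutoffs" in raw:
            raw["age_cutoffs"] = {int(k): float(v)
                                  for k, v in raw["age_cutoffs"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "scenario": self.scenario, "beta": self.beta,
            "n_families": self.n_families, "thresholds": dict(self.thresholds),
            "age_cutoffs": {str(k): v for k, v in self.age_cutoffs.items()},
            "alpha": self.alpha, "power": self.power, "outdir": self.outdir,
        }

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)       # where results land is not what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
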