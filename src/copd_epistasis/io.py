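"""Genotype / phenotype containers and text-file I/O.

Genotypes travel as PLINK text ``.ped``/``.map`` pairs (whitespace
delimited, allele code ``0`` for missing); phenotypes as a tidy
comma-separated table with ``NA`` marking unavailable cells.  Genotype
calls are additively coded: 0/1/2 copies of the minor allele, with
``MISSING = -1`` for no-calls.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

#: case/control labels accepted in phenotype files
STATUS_LEVELS = ("case", "control")

#: continuous traits, in the units used throughout the package
CONTINUOUS_TRAITS = ("fev1", "fev1_pct_pred", "fvc", "fev1_fvc", "six_mwt")

#: ordinal traits and their admissible integer ranges
ORDINAL_TRAIT_RANGES = {"mmrc": (0, 5), "bode": (0, 10)}

COVARIATES = ("age", "sex", "pack_years")

#: full phenotype-file schema, in column order
PHENOTYPE_COLUMNS = (
    ("subject_id",) + ("status",) + COVARIATES + ("bmi",)
    + CONTINUOUS_TRAITS + tuple(ORDINAL_TRAIT_RANGES)
)


class PhenotypeValidationError(ValueError):
    """Raised when a phenotype table violates the schema; the message
    names the offending row (subject) and column."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive genotype calls with SNP annotations.

    ``calls`` is an ``(n_subjects, n_snps)`` integer array with values in
    {0, 1, 2, MISSING}; ``snp_meta`` holds one row per SNP with at least
    ``snp_id``, ``gene_block``, ``chrom``, ``position``, ``major_allele``
    and ``minor_allele`` columns, in column order of ``calls``.
    """

    subject_ids: np.ndarray
    snp_meta: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-dimensional")
        n, s = self.calls.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match calls rows")
        if len(self.snp_meta) != s:
            raise ValueError("snp_meta rows must match calls columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        ids = list(self.snp_meta["snp_id"])
        if len(set(ids)) != s:
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, MISSING}")

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        """Calls for one SNP, by id."""
        return self.calls[:, self.snp_index(snp_id)]

    def snp_index(self, snp_id: str) -> int:
        ids = self.snp_ids
        try:
            return ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def maf(self) -> np.ndarray:
        """Observed minor-allele frequency per SNP (folded to <= 0.5)."""
        return np.array([compute_maf(self.calls[:, j])
                         for j in range(self.n_snps)])


@dataclass
class PhenotypeTable:
    """Trait, covariate and disease-status table, one row per subject.

    Missing/unavailable cells (e.g. 6MWT for controls) are ``NaN`` in the
    frame and written out as ``NA``.  Ordinal traits are validated to
    their integer ranges wherever non-missing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("subject_id", "status") + COVARIATES:
            if col not in df.columns:
                raise PhenotypeValidationError(f"missing required column '{col}'")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise PhenotypeValidationError(f"duplicate subject_id '{dup}'")
        bad_status = ~df["status"].isin(STATUS_LEVELS)
        if bad_status.any():
            i = int(np.flatnonzero(bad_status)[0])
            raise PhenotypeValidationError(
                f"row {i} (subject {df['subject_id'].iloc[i]!r}), column "
                f"'status': unknown label {df['status'].iloc[i]!r}"
            )
        for col, (lo, hi) in ORDINAL_TRAIT_RANGES.items():
            if col not in df.columns:
                continue
            vals = df[col]
            ok = vals.isna() | (
                (vals >= lo) & (vals <= hi) & (vals == np.floor(vals))
            )
            if not ok.all():
                i = int(np.flatnonzero(~ok)[0])
                raise PhenotypeValidationError(
                    f"row {i} (subject {df['subject_id'].iloc[i]!r}), column "
                    f"'{col}': value {vals.iloc[i]!r} outside {lo}..{hi}"
                )
        self.df = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy(dtype=object)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def case_mask(self) -> np.ndarray:
        return (self.df["status"] == "case").to_numpy()

    def trait(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(f"unknown trait '{name}'")
        return self.df[name].to_numpy(dtype=float)

    def covariate_frame(self) -> pd.DataFrame:
        return self.df[list(COVARIATES)].astype(float)


def compute_maf(calls: np.ndarray) -> float:
    """Minor-allele frequency of one additive genotype column.

    The frequency is the minor-allele count over ``2 x`` the non-missing
    subject count, folded to <= 0.5 (so it is invariant to which allele
    label the column happens to count).
    """
    calls = np.asarray(calls)
    ok = calls != MISSING
    if not ok.any():
        raise ValueError("all calls missing for this SNP")
    f = calls[ok].sum() / (2.0 * ok.sum())
    return float(min(f, 1.0 - f))


# ---------------------------------------------------------------------------
# PLINK text .ped / .map

def write_ped_map(
    geno: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    phenotypes: PhenotypeTable | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a genotype matrix as a PLINK text ``.ped``/``.map`` pair.

    Genotype g is expanded to allele pairs: 0 -> major/major, 1 ->
    minor/major, 2 -> minor/minor, MISSING -> ``0 0``.  If a phenotype
    table is given, the .ped sex column is 1/2 (0 unknown) and the
    phenotype column is 2 for cases, 1 for controls.
    """
    meta = geno.snp_meta
    with open(map_path, "w") as fh:
        for _, row in meta.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{int(row['position'])}\n")

    pheno_by_id = {}
    if phenotypes is not None:
        for _, row in phenotypes.df.iterrows():
            sex = row["sex"]
            sex_code = 0 if pd.isna(sex) else (2 if int(sex) == 1 else 1)
            pheno_by_id[row["subject_id"]] = (
                sex_code, 2 if row["status"] == "case" else 1
            )

    major = meta["major_allele"].to_numpy()
    minor = meta["minor_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.subject_ids):
            sex_code, phe = pheno_by_id.get(sid, (0, -9))
            fields = [str(sid), str(sid), "0", "0", str(sex_code), str(phe)]
            row = geno.calls[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [major[j], major[j]]
                elif g == 1:
                    fields += [minor[j], major[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")

    _write_sidecar(ped_path, provenance)


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    minor_alleles: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a PLINK text ``.ped``/``.map`` pair into additive coding.

    By default the minor allele of each SNP is recomputed from the file
    (the allele with frequency <= 0.5; exact ties broken toward the
    lexicographically larger allele letter).  Pass ``minor_alleles``
    (snp_id -> allele letter) to respect external panel metadata instead.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed .map line: {line!r}")
            map_rows.append(parts)
    snp_ids = [r[1] for r in map_rows]
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP ids in .map")
    n_snps = len(snp_ids)

    subject_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f".ped line {lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            subject_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(subject_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_snps, 2)
    valid = {"A", "C", "G", "T", "0"}
    unknown = set(alleles.ravel()) - valid
    if unknown:
        raise ValueError(f"unknown allele symbols: {sorted(unknown)}")

    calls = np.empty((n, n_snps), dtype=np.int8)
    minor_used: list[str] = []
    major_used: list[str] = []
    for j, snp_id in enumerate(snp_ids):
        a = alleles[:, j, :]
        missing = (a == "0").any(axis=1)
        observed = a[~missing].ravel()
        letters, counts = np.unique(observed, return_counts=True)
        if len(letters) > 2:
            raise ValueError(f"SNP {snp_id}: more than two alleles")
        if minor_alleles is not None and snp_id in minor_alleles:
            minor = minor_alleles[snp_id]
        elif len(letters) == 2:
            # lower-frequency allele is minor; exact tie -> larger letter
            if counts[0] != counts[1]:
                minor = str(letters[int(np.argmin(counts))])
            else:
                minor = str(max(letters))
        else:
            # all-missing or monomorphic column: no observable minor allele
            minor = ""
        g = (a == minor).sum(axis=1).astype(np.int8)
        g[missing] = MISSING
        calls[:, j] = g
        minor_used.append(minor)
        majors = [str(let) for let in letters if str(let) != minor]
        major_used.append(majors[0] if majors else "")

    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene_block": ["" for _ in snp_ids],
            "chrom": [r[0] for r in map_rows],
            "position": [int(r[3]) for r in map_rows],
            "major_allele": major_used,
            "minor_allele": minor_used,
        }
    )
    return GenotypeMatrix(np.array(subject_ids, dtype=object), meta, calls)


# ---------------------------------------------------------------------------
# Phenotype CSV

def write_phenotypes_csv(
    pheno: PhenotypeTable, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a phenotype table as UTF-8 CSV with ``NA`` missing markers."""
    cols = [c for c in PHENOTYPE_COLUMNS if c in pheno.df.columns]
    cols += [c for c in pheno.df.columns if c not in cols]
    # repr on write + round_trip parsing on read preserve full precision
    pheno.df[cols].to_csv(path, index=False, na_rep="NA",
                          float_format=lambda v: repr(float(v)))
    _write_sidecar(path, provenance)


def read_phenotypes_csv(path: str | Path) -> PhenotypeTable:
    """Read a phenotype CSV written by :func:`write_phenotypes_csv`.

    Validation failures raise :class:`PhenotypeValidationError` naming
    the row and column.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"subject_id": str, "status": str})
    return PhenotypeTable(df)


def align_cohort(geno: GenotypeMatrix, pheno: PhenotypeTable) -> None:
    """Check that genotype and phenotype subjects agree one-to-one.

    Subjects present in only one input are an error (silent
    intersection would corrupt cross-validation folds downstream).
    """
    g = set(geno.subject_ids)
    p = set(pheno.subject_ids)
    if g != p:
        only_g = sorted(g - p)[:5]
        only_p = sorted(p - g)[:5]
        raise ValueError(
            "genotype/phenotype subject mismatch: "
            f"{len(g - p)} only in genotypes (e.g. {only_g}), "
            f"{len(p - g)} only in phenotypes (e.g. {only_p})"
        )
    if list(geno.subject_ids) != list(pheno.subject_ids):
        raise ValueError("genotype and phenotype subject order differs")


def _write_sidecar(path: str | Path, provenance: dict | None) -> None:
    """Emit ``<path>.provenance.json`` describing how a file was made."""
    info = dict(provenance or {})
    info.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S%z"))
    if "config" in info and not isinstance(info["config"], str):
        blob = json.dumps(info["config"], sort_keys=True, default=str)
        info["config_sha1"] = hashlib.sha1(blob.encode()).hexdigest()
        del info["config"]
    with open(str(path) + ".provenance.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
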