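"""Single-marker additive QTL scan with Bonferroni correction.

Each SNP is tested against each quantitative trait with an ordinary
least-squares model ``trait ~ genotype + age + sex + pack_years`` where
genotype enters additively (0/1/2 minor-allele count).  The two-sided p
of the genotype coefficient is corrected over the number of SNPs tested
(m = 44 for the default panel): ``p_bonf = min(1, m * p_raw)``.  Fits go
through statsmodels OLS; subjects missing any required field are
dropped per (SNP, trait) pair and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MISSING, COVARIATES, GenotypeMatrix, PhenotypeTable
from .summary import round_half_up

__all__ = ["QTLResult", "fit_additive_model", "bonferroni", "run_scan"]


@dataclass(frozen=True)
class QTLResult:
    """One (SNP, trait) additive-model association."""

    snp_id: str
    trait_name: str
    beta: float          # trait units per minor allele
    se: float
    t_stat: float
    p_raw: float
    n_used: int
    p_bonferroni: float | None = None


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-corrected p: ``min(1, m * p_raw)``.

    Monotone in both arguments, never exceeds 1.  Printed reports round
    the result half-up to 3 decimals (see :func:`run_scan`).
    """
    if not 0.0 < p_raw <= 1.0:
        raise ValueError("p_raw must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def fit_additive_model(
    trait_values,
    genotype_column,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
    trait_name: str = "",
) -> QTLResult:
    """OLS of trait on {intercept, genotype, age, sex, pack-years}.

    Complete-case: subjects with a missing genotype, trait or covariate
    are dropped.  Raises for a monomorphic genotype column or a
    rank-deficient design.
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(genotype_column, dtype=float)
    mask = np.isfinite(y) & (g != MISSING)
    cov = None
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float)
        mask &= np.isfinite(cov).all(axis=1)
    y, g = y[mask], g[mask]
    if np.unique(g).size < 2:
        raise ValueError(f"monomorphic genotype column '{snp_id}'")
    X = g[:, None] if cov is None else np.column_stack([g, cov[mask]])
    X = sm.add_constant(X, prepend=True)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return QTLResult(
        snp_id=snp_id,
        trait_name=trait_name,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_stat=float(fit.tvalues[1]),
        p_raw=float(fit.pvalues[1]),
        n_used=int(len(y)),
    )


def run_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    traits: list[str],
    m: int | None = None,
    subjects: str = "cases",
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Scan every SNP against every trait; one row per (SNP, trait).

    ``m`` defaults to the number of SNPs tested (not SNPs x traits —
    the correction is per-trait over the panel).  ``subjects`` selects
    ``"cases"`` or ``"all"``.  Output flags ``sig_raw`` (p_raw < 0.05)
    and ``sig_bonferroni`` (corrected < 0.05), and carries the corrected
    p both exact and printed to 3 decimals half-up.
    """
    if genotypes.n_snps < 1 or not traits:
        raise ValueError("need at least one SNP and one trait")
    if subjects == "cases":
        keep = phenotypes.case_mask()
    elif subjects == "all":
        keep = np.ones(phenotypes.n_subjects, dtype=bool)
    else:
        raise ValueError("subjects must be 'cases' or 'all'")
    if not keep.any():
        raise ValueError("empty cohort after subject selection")

    m_eff = genotypes.n_snps if m is None else int(m)
    cov = phenotypes.covariate_frame().loc[keep] if adjust_covariates else None
    rows = []
    for trait in traits:
        y = phenotypes.trait(trait)[keep]
        for j, snp_id in enumerate(genotypes.snp_ids):
            g = genotypes.calls[keep, j]
            res = fit_additive_model(y, g, cov, snp_id=snp_id, trait_name=trait)
            p_bonf = bonferroni(res.p_raw, m_eff)
            rows.append(
                {
                    "trait": trait,
                    "snp_id": snp_id,
                    "gene_block": genotypes.snp_meta["gene_block"].iloc[j],
                    "beta": res.beta,
                    "se": res.se,
                    "t_stat": res.t_stat,
                    "p_raw": res.p_raw,
                    "p_bonferroni": p_bonf,
                    "p_bonferroni_printed": round_half_up(p_bonf, 3),
                    "n_used": res.n_used,
                    "sig_raw": res.p_raw < 0.05,
                    "sig_bonferroni": p_bonf < 0.05,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["m"] = m_eff
    return out
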