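"""Synthetic COPD cohort generator.

The study design being emulated: 44 tag SNPs (MAF > 0.05) in four gene
blocks with within-block linkage disequilibrium, 310 COPD cases plus 203
controls, spirometric case definition (FEV1/FVC < 0.7 and FEV1%pre <
0.8 of predicted), covariates age / sex / pack-years, seven quantitative
traits for cases and the four lung-function traits for controls.
Genetic signal is planted through per-trait effect specifications that
allow additive single-SNP slopes and arbitrary multi-locus cell-mean
offsets (including pure epistasis with zero marginal effects).

All randomness flows from a single integer seed through a hierarchical
``numpy.random.SeedSequence`` spawn, so identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    align_cohort,
)
from .panel import SnpPanel, default_panel

__all__ = [
    "EffectSpec",
    "EpistasisTerm",
    "Cohort",
    "CohortConfig",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_traits",
    "simulate_cohort",
    "derive_bode",
    "assign_disease_status",
    "checkerboard_epistasis",
    "default_case_specs",
    "default_control_specs",
]

#: cutpoints on the standard-normal MMRC latent severity scale; chosen so
#: a null latent reproduces a mild dyspnea profile (most mass on grades
#: 0-2, almost none on grade 5)
DEFAULT_MMRC_CUTPOINTS = (-0.962, 0.340, 1.305, 1.546, 3.9)


@dataclass(frozen=True)
class EpistasisTerm:
    """A multi-locus cell-mean shift.

    ``offsets`` maps genotype tuples (each coordinate in {0,1,2}, one per
    SNP in ``snp_tuple``) to a trait-unit shift; tuples not listed get 0.
    A term whose row/column marginal averages are all zero is *pure*
    epistasis: no single-SNP additive model can see it.
    """

    snp_tuple: tuple[str, ...]
    offsets: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        k = len(self.snp_tuple)
        for cell in self.offsets:
            if len(cell) != k or any(g not in (0, 1, 2) for g in cell):
                raise ValueError(f"bad genotype cell {cell} for k={k} term")


@dataclass
class EffectSpec:
    """Generative model of one continuous trait (or ordinal latent).

    trait = intercept + covariates . betas + additive SNP effects
            + epistatic cell offsets + Normal(0, noise_sd).
    """

    trait_name: str
    intercept: float = 0.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    main_effects: dict[str, float] = field(default_factory=dict)
    epistasis_terms: list[EpistasisTerm] = field(default_factory=list)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class Cohort:
    """A simulated (or loaded) genotype + phenotype pair."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    seed: int | None = None

    def __post_init__(self) -> None:
        align_cohort(self.genotypes, self.phenotypes)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects


def checkerboard_epistasis(
    snp_a: str, snp_b: str, offset: float
) -> EpistasisTerm:
    """A pure-epistasis pair term: +offset on even-parity genotype cells,
    -offset on odd-parity cells.

    When both SNPs have MAF 0.5 (so heterozygotes have probability 1/2),
    every single-SNP marginal of this pattern is exactly zero while the
    joint cell means separate by 2*offset.
    """
    offsets = {
        (a, b): (offset if (a + b) % 2 == 0 else -offset)
        for a in (0, 1, 2)
        for b in (0, 1, 2)
    }
    return EpistasisTerm((snp_a, snp_b), offsets)


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(
    n: int,
    panel: SnpPanel,
    seed: int | np.random.SeedSequence,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw additive genotypes for ``n`` subjects under block LD.

    Each subject carries two independent haplotypes.  Within a block the
    haplotypes follow a copy-chain: SNP j shares SNP j-1's latent
    uniform draw with probability ``block_ld_rho`` (else draws fresh), and
    the allele indicator is ``u < maf``.  Sharing the uniform rather than
    the allele value keeps every SNP's marginal frequency exactly at its
    panel MAF even when MAFs differ along the chain; for equal MAFs the
    scheme reduces to allele copying, with haplotype correlation rho and
    pairwise LD r^2 = rho^2 between neighbours.  Blocks are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)

    calls = np.empty((n, len(panel)), dtype=np.int8)
    col = 0
    for gene in panel.gene_blocks:
        block = panel.block(gene)
        hap = np.zeros((2, n, len(block)), dtype=np.int8)
        for h in (0, 1):
            u_prev: np.ndarray | None = None
            for j, snp in enumerate(block):
                u = rng.uniform(size=n)
                if j > 0 and snp.block_ld_rho > 0:
                    copy = rng.uniform(size=n) < snp.block_ld_rho
                    u = np.where(copy, u_prev, u)
                hap[h, :, j] = u < snp.maf
                u_prev = u
        g = hap.sum(axis=0, dtype=np.int8)
        calls[:, col : col + len(block)] = g
        col += len(block)

    if missing_rate > 0:
        mask = rng.uniform(size=calls.shape) < missing_rate
        calls[mask] = MISSING

    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(subject_ids, panel.meta_frame(), calls)


# ---------------------------------------------------------------------------
# covariates

def simulate_covariates(
    n: int,
    seed: int | np.random.SeedSequence,
    pack_years_shape: float = 2.0,
    pack_years_scale: float = 12.5,
    sex_p: float = 0.5,
) -> pd.DataFrame:
    """Draw age (uniform 40-75 years), sex (0/1) and pack-years (gamma).

    The age range matches the study's recruitment window; the gamma
    pack-years shape is a documented free choice (mean 25 by default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    return pd.DataFrame(
        {
            "age": rng.uniform(40.0, 75.0, size=n),
            "sex": (rng.uniform(size=n) < sex_p).astype(int),
            "pack_years": rng.gamma(pack_years_shape, pack_years_scale, size=n),
        }
    )


# ---------------------------------------------------------------------------
# traits

def _spec_values(
    spec: EffectSpec,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    n = geno.n_subjects
    y = np.full(n, spec.intercept, dtype=float)
    for cov, beta in spec.covariate_betas.items():
        if cov not in covariates.columns:
            raise KeyError(f"spec '{spec.trait_name}': unknown covariate '{cov}'")
        y += beta * covariates[cov].to_numpy(dtype=float)
    for snp_id, beta in spec.main_effects.items():
        y += beta * geno.column(snp_id)  # raises KeyError for unknown SNP
    for term in spec.epistasis_terms:
        cols = np.column_stack([geno.column(s) for s in term.snp_tuple])
        if (cols == MISSING).any():
            raise ValueError(
                f"spec '{spec.trait_name}': epistasis term on SNPs with "
                "missing genotypes"
            )
        for cell, off in term.offsets.items():
            if off != 0.0:
                y += off * (cols == np.asarray(cell)).all(axis=1)
    y += rng.normal(0.0, spec.noise_sd, size=n)
    return y


def simulate_traits(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    specs: dict[str, EffectSpec],
    seed: int | np.random.SeedSequence,
    status: str = "case",
    mmrc_cutpoints: tuple[float, ...] = DEFAULT_MMRC_CUTPOINTS,
) -> PhenotypeTable:
    """Generate the phenotype table for one cohort arm.

    ``specs`` must cover at least ``fev1``, ``fvc`` and ``fev1_pct_pred``
    (percent-of-predicted scale).  Derived columns: ``fev1_fvc`` is the
    generated FEV1/FVC ratio clamped to (0, 1]; ``mmrc`` thresholds the
    latent severity spec ``mmrc_latent`` at ``mmrc_cutpoints``;
    ``six_mwt`` is clipped at 0; ``bode`` comes from :func:`derive_bode`.
    For controls (``status="control"``) the case-only traits (6MWT,
    MMRC, BODE) are marked unavailable (NaN), never silently zero.
    """
    for required in ("fev1", "fvc", "fev1_pct_pred"):
        if required not in specs:
            raise ValueError(f"specs must include '{required}'")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)

    df = pd.DataFrame({"subject_id": genotypes.subject_ids})
    df["status"] = status
    for cov in ("age", "sex", "pack_years"):
        df[cov] = covariates[cov].to_numpy()

    cont: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        cont[name] = _spec_values(spec, genotypes, covariates, rng)

    fev1 = np.maximum(cont["fev1"], 0.05)
    fvc = np.maximum(cont["fvc"], 0.10)
    pct = np.clip(cont["fev1_pct_pred"], 5.0, 150.0)
    df["bmi"] = np.maximum(cont.get("bmi", rng.normal(23.0, 3.5, len(df))), 12.0)
    df["fev1"] = fev1
    df["fev1_pct_pred"] = pct
    df["fvc"] = fvc
    df["fev1_fvc"] = np.clip(fev1 / fvc, None, 1.0)

    if status == "case":
        six_mwt = cont.get("six_mwt")
        if six_mwt is None:
            six_mwt = rng.normal(400.0, 90.0, len(df))
        six_mwt = np.maximum(six_mwt, 0.0)
        latent = cont.get("mmrc_latent")
        if latent is None:
            latent = rng.normal(size=len(df))
        mmrc = np.searchsorted(np.asarray(mmrc_cutpoints), latent, side="left")
        mmrc = np.clip(mmrc, 0, 5)
        df["six_mwt"] = six_mwt
        df["mmrc"] = mmrc.astype(float)
        df["bode"] = derive_bode(
            df["bmi"].to_numpy(), pct, mmrc, six_mwt
        ).astype(float)
    else:
        df["six_mwt"] = np.nan
        df["mmrc"] = np.nan
        df["bode"] = np.nan

    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# clinical scores and case definition

def derive_bode(bmi, fev1_pct_pred, mmrc_grade, six_mwd):
    """BODE index (0-10): BMI + airflow obstruction + dyspnea + exercise.

    Standard banding: BMI <= 21 scores 1 (else 0); FEV1%pre >= 65 / 50-64
    / 36-49 / <= 35 scores 0/1/2/3; MMRC grade 0-1 / 2 / 3 / 4-5 scores
    0/1/2/3; 6-minute walk distance >= 350 / 250-349 / 150-249 / <= 149 m
    scores 0/1/2/3.  Accepts scalars or arrays; FEV1%pre is on the
    percent scale here.
    """
    bmi = np.asarray(bmi, dtype=float)
    pct = np.asarray(fev1_pct_pred, dtype=float)
    mmrc = np.asarray(mmrc_grade)
    walk = np.asarray(six_mwd, dtype=float)
    scalar = bmi.ndim == 0
    bmi, pct, mmrc, walk = np.atleast_1d(bmi, pct, mmrc, walk)

    if (bmi <= 0).any():
        raise ValueError("bmi must be > 0")
    if ((pct <= 0) | (pct > 150)).any():
        raise ValueError("fev1_pct_pred must be in (0, 150] percent")
    if (np.floor(mmrc) != mmrc).any() or ((mmrc < 0) | (mmrc > 5)).any():
        raise ValueError("mmrc_grade must be an integer in 0..5")
    if (walk < 0).any():
        raise ValueError("six_mwd must be >= 0")

    b = (bmi <= 21).astype(int)
    o = np.select([pct >= 65, pct >= 50, pct >= 36], [0, 1, 2], default=3)
    d = np.select([mmrc <= 1, mmrc == 2, mmrc == 3], [0, 1, 2], default=3)
    e = np.select([walk >= 350, walk >= 250, walk >= 150], [0, 1, 2], default=3)
    total = b + o + d + e
    return int(total[0]) if scalar else total


def assign_disease_status(fev1_fvc_ratio, fev1_pct_pred):
    """Spirometric COPD case definition.

    A subject is a case iff FEV1/FVC < 0.7 AND FEV1%pre < 0.8 of
    predicted (both inequalities strict; both arguments on the fraction
    scale).  Returns ``"case"``/``"control"`` (array for array input).
    """
    ratio = np.asarray(fev1_fvc_ratio, dtype=float)
    pct = np.asarray(fev1_pct_pred, dtype=float)
    scalar = ratio.ndim == 0 and pct.ndim == 0
    ratio, pct = np.atleast_1d(ratio, pct)
    if (ratio <= 0).any() or (pct <= 0).any():
        raise ValueError("inputs must be positive")
    out = np.where((ratio < 0.7) & (pct < 0.8), "case", "control")
    return str(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# whole-cohort assembly

def default_case_specs(panel: SnpPanel | None = None) -> dict[str, EffectSpec]:
    """Trait models for the COPD arm (no genetic effects by default).

    Intercepts/slopes place the arm firmly below the diagnostic
    thresholds: mean FEV1 around 1.5 L, FEV1%pre around 48 %, FEV1/FVC
    around 0.55.
    """
    return {
        "fev1": EffectSpec(
            "fev1", intercept=3.1,
            covariate_betas={"age": -0.022, "sex": -0.25, "pack_years": -0.006},
            noise_sd=0.35,
        ),
        "fvc": EffectSpec(
            "fvc", intercept=4.5,
            covariate_betas={"age": -0.025, "sex": -0.40, "pack_years": -0.004},
            noise_sd=0.45,
        ),
        "fev1_pct_pred": EffectSpec(
            "fev1_pct_pred", intercept=68.0,
            covariate_betas={"age": -0.30, "pack_years": -0.10},
            noise_sd=11.0,
        ),
        "six_mwt": EffectSpec(
            "six_mwt", intercept=540.0,
            covariate_betas={"age": -2.0, "pack_years": -0.5},
            noise_sd=80.0,
        ),
        "mmrc_latent": EffectSpec("mmrc_latent", intercept=0.0, noise_sd=1.0),
        "bmi": EffectSpec("bmi", intercept=23.0, noise_sd=3.5),
    }


def default_control_specs(panel: SnpPanel | None = None) -> dict[str, EffectSpec]:
    """Trait models for the control arm: normal lung function."""
    return {
        "fev1": EffectSpec(
            "fev1", intercept=4.4,
            covariate_betas={"age": -0.025, "sex": -0.35},
            noise_sd=0.35,
        ),
        "fvc": EffectSpec(
            "fvc", intercept=5.3,
            covariate_betas={"age": -0.028, "sex": -0.45},
            noise_sd=0.40,
        ),
        "fev1_pct_pred": EffectSpec(
            "fev1_pct_pred", intercept=105.0,
            covariate_betas={"age": -0.20},
            noise_sd=8.0,
        ),
        "bmi": EffectSpec("bmi", intercept=24.0, noise_sd=3.2),
    }


@dataclass
class CohortConfig:
    """Everything needed to draw one case/control cohort."""

    panel: SnpPanel = field(default_factory=default_panel)
    n_cases: int = 310
    n_controls: int = 203
    case_specs: dict[str, EffectSpec] | None = None
    control_specs: dict[str, EffectSpec] | None = None
    missing_rate: float = 0.0
    case_pack_years_scale: float = 15.0
    control_pack_years_scale: float = 7.5
    max_rounds: int = 60


def _simulate_arm(
    config: CohortConfig,
    status: str,
    n_target: int,
    seq: np.random.SeedSequence,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Rejection-sample one arm until ``n_target`` subjects satisfy the
    spirometric definition of that arm."""
    specs = (
        (config.case_specs or default_case_specs(config.panel))
        if status == "case"
        else (config.control_specs or default_control_specs(config.panel))
    )
    py_scale = (
        config.case_pack_years_scale if status == "case"
        else config.control_pack_years_scale
    )
    kept_calls, kept_rows = [], []
    n_kept = 0
    for round_no in range(config.max_rounds):
        batch = max(32, int(1.6 * (n_target - n_kept)))
        # per-round children of the arm sequence, independent of how many
        # rounds earlier arms needed
        g_seq, c_seq, t_seq = np.random.SeedSequence(
            entropy=seq.entropy, spawn_key=seq.spawn_key + (round_no,)
        ).spawn(3)
        geno = simulate_genotypes(batch, config.panel, g_seq,
                                  missing_rate=config.missing_rate)
        cov = simulate_covariates(batch, c_seq, pack_years_scale=py_scale)
        pheno = simulate_traits(geno, cov, specs, t_seq, status=status)
        got = assign_disease_status(
            pheno.df["fev1_fvc"].to_numpy(),
            pheno.df["fev1_pct_pred"].to_numpy() / 100.0,
        )
        keep = got == status
        if keep.any():
            kept_calls.append(geno.calls[keep])
            kept_rows.append(pheno.df.loc[keep])
            n_kept += int(keep.sum())
        if n_kept >= n_target:
            break
    else:
        raise RuntimeError(
            f"could not draw {n_target} '{status}' subjects in "
            f"{config.max_rounds} rounds; arm trait specs are inconsistent "
            "with the spirometric thresholds"
        )
    calls = np.concatenate(kept_calls)[:n_target]
    df = pd.concat(kept_rows).iloc[:n_target].reset_index(drop=True)
    prefix = "case" if status == "case" else "ctrl"
    ids = np.array([f"{prefix}{i + 1:04d}" for i in range(n_target)], dtype=object)
    df["subject_id"] = ids
    geno_out = GenotypeMatrix(ids, config.panel.meta_frame(), calls)
    return geno_out, PhenotypeTable(df)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> Cohort:
    """Draw a full case/control cohort under ``config`` (study defaults:
    310 cases + 203 controls on the 44-SNP panel).

    Case/control membership is enforced by rejection: each arm keeps
    drawing subjects from its own trait model until the requested number
    satisfy :func:`assign_disease_status` for that arm, so the printed
    sample sizes are exact and the labels are honest functions of the
    generated spirometry.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    case_seq, ctrl_seq = root.spawn(2)
    case_g, case_p = _simulate_arm(config, "case", config.n_cases, case_seq)
    ctrl_g, ctrl_p = _simulate_arm(config, "control", config.n_controls, ctrl_seq)

    calls = np.concatenate([case_g.calls, ctrl_g.calls])
    ids = np.concatenate([case_g.subject_ids, ctrl_g.subject_ids])
    geno = GenotypeMatrix(ids, config.panel.meta_frame(), calls)
    df = pd.concat([case_p.df, ctrl_p.df]).reset_index(drop=True)
    return Cohort(geno, PhenotypeTable(df), seed=seed)
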