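"""Tag-SNP panel description.

A panel is the list of biallelic SNPs the study genotypes: each SNP
belongs to a gene block (EPHX1, GSTP1, SERPINE2 or TGFB1 in the default
panel), has a minor-allele frequency (MAF), and a within-block linkage
parameter ``block_ld_rho`` that controls how strongly its haplotype
allele is correlated with the previous SNP of the same block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_BLOCK_LD_RHO = 0.6

#: chromosome of each default gene block (human assembly, informational only)
GENE_CHROMOSOMES = {"EPHX1": "1", "GSTP1": "11", "SERPINE2": "2", "TGFB1": "19"}


@dataclass(frozen=True)
class Snp:
    """One biallelic tag SNP.

    ``block_ld_rho`` is the probability that this SNP's haplotype allele
    is copied from the previous SNP in the same gene block (ignored for
    the first SNP of a block).
    """

    snp_id: str
    gene_block: str
    major_allele: str
    minor_allele: str
    maf: float
    block_ld_rho: float = DEFAULT_BLOCK_LD_RHO
    chrom: str = "0"
    position: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(
                f"SNP {self.snp_id}: maf must be in (0, 0.5], got {self.maf}"
            )
        if not (0.0 <= self.block_ld_rho < 1.0):
            raise ValueError(
                f"SNP {self.snp_id}: block_ld_rho must be in [0, 1), "
                f"got {self.block_ld_rho}"
            )
        if self.major_allele == self.minor_allele:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


@dataclass
class SnpPanel:
    """An ordered collection of tag SNPs grouped into gene blocks."""

    snps: list[Snp] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique")
        low = [s.snp_id for s in self.snps if s.maf <= 0.05]
        if low:
            raise ValueError(
                f"panel SNPs must have MAF > 0.05; offending: {low}"
            )

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def gene_blocks(self) -> list[str]:
        seen: list[str] = []
        for s in self.snps:
            if s.gene_block not in seen:
                seen.append(s.gene_block)
        return seen

    def block(self, gene: str) -> list[Snp]:
        return [s for s in self.snps if s.gene_block == gene]

    def meta_frame(self) -> pd.DataFrame:
        """Per-SNP annotation table in panel order."""
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "gene_block": [s.gene_block for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "position": [s.position for s in self.snps],
                "major_allele": [s.major_allele for s in self.snps],
                "minor_allele": [s.minor_allele for s in self.snps],
                "maf": [s.maf for s in self.snps],
            }
        )


# rs numbers of the tag SNPs the study names; the *_tag fillers pad each
# block to the full 44-SNP design (13 EPHX1 + 5 GSTP1 + 19 SERPINE2 +
# 7 TGFB1) where the remaining ids are not public.
_DEFAULT_SNP_IDS: dict[str, list[str]] = {
    "EPHX1": [
        "rs1051740", "rs1051741", "rs1877724", "rs2234922", "rs2260863",
        "rs2292558", "rs2292568", "rs2854450", "rs3738040", "rs3766934",
        "rs41266229", "rs868966", "EPHX1_tag13",
    ],
    "GSTP1": [
        "rs1138272", "rs36211088", "rs4147581", "rs947895", "GSTP1_tag5",
    ],
    "SERPINE2": [
        "rs10191694", "rs13392495", "rs17196253", "rs2118409", "rs282254",
        "rs3820766", "rs4674841", "rs4674843", "rs6712954", "rs6734100",
        "rs6736436", "rs6738983", "rs6748795", "rs729631", "rs7579646",
        "rs7583463", "rs861442", "rs975278", "SERPINE2_tag19",
    ],
    "TGFB1": [
        "rs1800469", "rs2241713", "rs2241715", "rs2241718", "rs6957",
        "TGFB1_tag6", "TGFB1_tag7",
    ],
}

_MAF_CYCLE = (0.12, 0.27, 0.41, 0.09, 0.33, 0.18, 0.45, 0.22,
              0.36, 0.15, 0.29, 0.48, 0.11, 0.25)
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T"))


def default_panel(block_ld_rho: float = DEFAULT_BLOCK_LD_RHO) -> SnpPanel:
    """The default 44-SNP, 4-gene tag panel.

    Allele letters and MAFs are deterministic placeholders (the study's
    cohort-specific frequencies are not public); MAFs cycle through a
    fixed set of values in (0.05, 0.5] so the panel exercises the whole
    admissible range.
    """
    snps: list[Snp] = []
    i = 0
    for gene, ids in _DEFAULT_SNP_IDS.items():
        for j, snp_id in enumerate(ids):
            major, minor = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
            snps.append(
                Snp(
                    snp_id=snp_id,
                    gene_block=gene,
                    major_allele=major,
                    minor_allele=minor,
                    maf=_MAF_CYCLE[i % len(_MAF_CYCLE)],
                    block_ld_rho=block_ld_rho,
                    chrom=GENE_CHROMOSOMES.get(gene, "0"),
                    position=1_000_000 + 1_000 * j,
                )
            )
            i += 1
    panel = SnpPanel(snps)
    assert len(panel) == 44
    return panel


def make_panel(
    n_snps: int,
    n_blocks: int = 1,
    maf: float | list[float] = 0.3,
    block_ld_rho: float = DEFAULT_BLOCK_LD_RHO,
    prefix: str = "snp",
) -> SnpPanel:
    """Build a small ad-hoc panel (mainly for simulations and tests).

    SNPs are distributed over ``n_blocks`` blocks named ``block1`` ...;
    ``maf`` may be a scalar or a per-SNP list.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    mafs = [maf] * n_snps if isinstance(maf, float) else list(maf)
    if len(mafs) != n_snps:
        raise ValueError("maf list length must equal n_snps")
    snps = []
    for i in range(n_snps):
        block = f"block{(i * n_blocks) // n_snps + 1}"
        major, minor = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        snps.append(
            Snp(
                snp_id=f"{prefix}{i + 1:03d}",
                gene_block=block,
                major_allele=major,
                minor_allele=minor,
                maf=mafs[i],
                block_ld_rho=block_ld_rho,
                position=1_000 * (i + 1),
            )
        )
    return SnpPanel(snps)
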