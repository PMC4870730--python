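"""QMDR: find a pure epistatic interaction no single-marker scan sees.

Plants a checkerboard cell-mean pattern on an EPHX1 x TGFB1 SNP pair —
cells shift by +/- 1 noise SD but every single-SNP marginal is zero —
then runs the exhaustive two-way QMDR search with tenfold
cross-validation and a 199-permutation significance test.
"""

import dataclasses

import numpy as np

import copd_epistasis as ce
from copd_epistasis.simulate import _spec_values

pair = ("rs1051740", "rs6957")  # different gene blocks, so no LD leakage
# the checkerboard marginal vanishes exactly when the partner SNP is
# heterozygous half the time, i.e. at MAF 0.5
panel = ce.SnpPanel([
    dataclasses.replace(s, maf=0.5) if s.snp_id in pair else s
    for s in ce.default_panel().snps
])
geno = ce.simulate_genotypes(310, panel, seed=31)
cov = ce.simulate_covariates(310, seed=32)
spec = ce.EffectSpec(
    "fev1", intercept=1.5, noise_sd=0.35,
    covariate_betas={"age": -0.005, "pack_years": -0.002},
    epistasis_terms=[ce.checkerboard_epistasis(*pair, offset=0.35)],
)
y = _spec_values(spec, geno, cov, np.random.default_rng(33))

# single-marker check first: the pure interaction has no marginal signal
raw = [ce.fit_additive_model(y, geno.calls[:, j], cov).p_raw
       for j in range(geno.n_snps)]
print("smallest Bonferroni-corrected single-marker p:",
      round(min(ce.bonferroni(p, geno.n_snps) for p in raw), 3),
      "(nothing significant)")

res = ce.permutation_test(geno, y, cov, method="qmdr", k=2, B=199, seed=34)
m = res.model
print(f"\nQMDR best two-way model: {' x '.join(m.snp_tuple)}")
print(f"  T-CV score      {m.t_cv_score:.4f}   (mean held-out t statistic)")
print(f"  CV consistency  {m.cv_consistency}/10  (folds agreeing on the pair)")
print(f"  permuted p      {res.p:.3f}  (B = {len(res.null_stats)})")
print("\nA significant p with high consistency on the planted pair shows the "
      "search detecting an interaction that is invisible marginally.")
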