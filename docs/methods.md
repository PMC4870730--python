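# Methods

This note documents the statistical models, conventions and design
choices the package implements, in the order data flows through it.

## Synthetic cohort model

The generator emulates a candidate-gene COPD study design: 44 tag SNPs
(MAF > 0.05) in four gene blocks (13 EPHX1, 5 GSTP1, 19 SERPINE2,
7 TGFB1), 310 cases and 203 controls, covariates age, sex and
pack-years. Tag ids use the study genes' published rs numbers where
known; `*_tag` fillers pad each block. Panel MAFs and allele letters
are deterministic placeholders cycling over (0.05, 0.5] — the real
cohort's frequencies are not public and matching them is a non-goal.

**Genotypes.** Each subject carries two independent haplotypes. Within
a block, SNP *j* shares SNP *j−1*'s latent uniform draw with
probability ρ (`block_ld_rho`, default 0.6) and otherwise draws fresh;
the allele indicator is `u < maf`. Sharing the *uniform* rather than
the allele value keeps every SNP's marginal frequency exactly at its
panel MAF even when MAFs differ along the chain; for equal MAFs it
reduces to allele copying with haplotype correlation ρ and neighbour
LD r² = ρ². ρ = 0.6 (neighbour r² ≈ 0.36) reflects that tag SNPs
chosen under a pairwise r² = 0.8 threshold are only moderately
correlated with each other. Blocks are independent; there is no
population structure or Hardy–Weinberg violation by design.

**Covariates.** Age ~ Uniform(40, 75) years (the recruitment window);
sex ~ Bernoulli(0.5); pack-years ~ Gamma(shape 2, scale 12.5 —
cases use scale 15, controls 7.5). The control arm's covariate
distributions are undocumented in studies of this design; these are
declared defaults, not inferences.

**Traits.** Each continuous trait follows
`intercept + covariates·β + Σ additive SNP effects + Σ epistatic
cell offsets + N(0, σ)`. Epistasis terms assign an arbitrary
trait-unit offset to each multi-locus genotype cell; the checkerboard
helper (± offset by genotype parity) gives *pure* epistasis — all
single-SNP marginals exactly zero — when both SNPs have MAF 0.5.
Derived columns: FEV₁/FVC is the generated ratio clamped to (0, 1];
MMRC thresholds a standard-normal latent severity at fixed cutpoints
(−0.962, 0.340, 1.305, 1.546, 3.9), chosen once so a null latent gives
a mild-dyspnea profile concentrated on grades 0–2; BODE is the
standard 0–10 sum of points — BMI ≤ 21 (1 point), FEV₁%pre ≥ 65 / 50–64
/ 36–49 / ≤ 35 (0–3), MMRC 0–1 / 2 / 3 / 4–5 (0–3), 6-minute walk
≥ 350 / 250–349 / 150–249 / ≤ 149 m (0–3). Default arm intercepts are
calibrated so case means sit near FEV₁ 1.4 L, FEV₁%pre 48 %, FEV₁/FVC
0.50 and control means near 2.8 L / 93 % / 0.80.

**Case definition.** A subject is a case iff FEV₁/FVC < 0.7 **and**
FEV₁%pre < 0.8 of predicted, both strict (the clinical definition says
"less than"). Arms are drawn by rejection: each arm resamples until
the requested number of subjects satisfies its definition, so sample
sizes are exact and labels are honest functions of the generated
spirometry. 6MWT, MMRC and BODE are generated for cases only and
explicitly marked unavailable for controls.

**Reproducibility.** One integer seed feeds a hierarchical
`SeedSequence` spawn (arm → round → generator); identical seeds give
bit-identical cohorts.

What the generator does **not** emulate: genotyping error, missingness
patterns (a uniform missing rate is available but off by default),
trait measurement error structure, population stratification, or the
real cohort's LD and allele frequencies. Passing tests therefore
validate the *methods* under a plausible data-generating process, not
the study's cohort-specific findings — the actual best-model identities
of that cohort are not reproducible without its raw data.

## Single-marker scan

OLS of trait on {intercept, genotype 0/1/2, age, sex, pack-years}
(statsmodels), two-sided t-test on the genotype coefficient,
complete-case per (SNP, trait). All traits, including ordinal MMRC and
BODE, use the same linear model — an explicit assumption, flagged here,
since the alternative (ordinal regression) is not part of the design
being reproduced. Bonferroni uses m = number of SNPs tested (44 for the
default panel), not SNPs × traits: this is the only multiplier
consistent with published corrected values of this table style
(e.g. 2.27×10⁻⁵ → 0.001 and 0.023 → capped 1.000 at m = 44).
Corrected p-values are printed to three decimals, half-up.

## Ordinal summaries

Quantiles use the inverted-CDF (type-1) convention: the q-quantile is
the smallest level whose cumulative count reaches ⌈q·n⌉ (rank clamped
to [1, n]). For even n the median is the lower of the two middle
ranks' levels. This convention reproduces all six printed summary
values (medians 1 and 2; P5–P95 0–4 and 1–6) of the reference MMRC and
BODE count vectors, which is the only available evidence of the
original convention. Levels may be non-contiguous (a BODE level with
zero count is simply absent). Percentages round half-up to one
decimal. Group comparisons: one-way ANOVA for continuous traits,
Kruskal–Wallis for ordinal ones, α = 0.05.

## QMDR / GMDR engine

Both methods run on the residuals of
`trait ~ intercept + age + sex + pack-years` (plain centring when no
covariates are supplied). For GMDR these residuals are exactly the
identity-link null-model scores; for QMDR residualising is the
covariate mechanism (the method's mean-comparison semantics are
shift-invariant, so unadjusted and intercept-only-adjusted runs
coincide).

Per fold of a tenfold cross-validation (seeded uniform shuffle, no
stratification):

1. every k-tuple's cells are built on training subjects;
2. QMDR: cell High iff training cell mean > overall training mean;
   GMDR: cell High iff summed member scores > 0;
3. training statistic — QMDR: pooled-variance two-sample t between the
   pooled High and Low groups; GMDR: score-mass balanced accuracy
   ½(positive mass in High / total positive + negative mass in Low /
   total negative);
4. the fold selects the tuple with the best training statistic;
5. the testing statistic evaluates the *training-derived* labels on the
   held-out fold (sign preserved — held-out t statistics can be
   negative).

The winner is the most frequently selected tuple; **CV consistency** is
its selection count and the **T-CV score** is the mean of its ten
held-out statistics. The T-CV score is defined this way deliberately:
it is the only construction consistent with published sign-carrying
values (a training-score average could not be negative for a selected
model).

Numerical conventions, chosen for determinism and total rankings:

* ties — cell mean equal to overall mean → Low; cell score sum exactly
  0 → Low; per-fold selection ties → lexicographically first tuple;
  winner ties → larger mean testing statistic, then lexicographic;
* held-out subjects in cells unseen during training → Low (conservative;
  no test subject is discarded);
* zero-variance pooled groups cap the t statistic at ±10⁶ instead of
  ±∞; an empty pooled group or non-positive degrees of freedom yields
  the sentinel worst score −10⁶ (QMDR) / −1 (GMDR), so degenerate
  labellings always lose;
* candidate tuples enumerate lexicographically over sorted SNP ids;
* the search requires complete genotypes (drop or impute first) —
  per-tuple complete-case handling is available in the granular
  `partition_cells` path.

**Permutation test.** The observed statistic is the winner's T-CV
score. Each of B permutations shuffles the adjusted phenotype across
subjects (genotypes untouched, preserving LD — the standard MDR null),
re-draws the fold assignment, reruns the entire search and records the
permuted winner's statistic; p = (b + 1)/(B + 1) with b the count of
null statistics ≥ observed. Whether the original analyses re-drew
folds inside permutations is unknowable from published descriptions;
re-drawing is implemented because it treats fold noise as part of the
statistic being calibrated.

The engine is vectorised over tuples (cell assignment by base-3
encoding, per-fold statistics via bincount and masked matrix products);
its correctness is pinned by tests against a naive nested-loop
reimplementation to 1e-10 and against the granular per-tuple
operations.

## Problem sizes used in validation

The test suite and acceptance script validate at sizes chosen to give
stable rates while keeping runs convenient on a single CPU: engine
oracle equivalence at 6 SNPs × 60 subjects; permutation type-I error
at 200 replicates (tests) / 100 replicates (script) of n = 200,
10 SNPs, B = 99; pure-epistasis recovery at 50 / 30 replicates of
n = 500, 15 SNPs, offset 1 SD; null-scan calibration at 50 / 30
replicates of the 44-SNP panel at n = 310; the study-sized
planted-pair demonstration at n = 310, 44 SNPs, B = 199. Production
analyses would use B = 1000 as in the published design (the CLI
default).

## Known limitations

* GMDR's published description does not print its testing statistic's
  formula; the score-mass balanced accuracy implemented here is this
  package's documented interpretation of "score-related statistics".
* Ordinal traits are treated as continuous throughout the MDR path
  (as the published T-CV values for MMRC/BODE imply).
* No binary PLINK (.bed), VCF, imputation, dominance models, FDR
  alternatives, k > 3 tuning, or multivariate-phenotype extensions.
* Permutation p-values have granularity 1/(B+1); with B = 99 the
  smallest attainable p is 0.01.
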