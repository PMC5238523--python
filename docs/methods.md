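# Methods

This note records the statistical model the package implements, the numerical
choices behind it, what the synthetic data generator does and does not
emulate, and the design decisions that were genuinely open.

## The mixed model

All prediction runs fit

    y = X mu + Z g + e,   g ~ N(0, G sigma2_g),   e ~ N(0, R sigma2_e)

* `y` — de-regressed proofs (DRP) of the training individuals for one trait.
  Multiple records per individual are allowed (Z then has repeated rows).
* `X` — a column of ones; the overall mean is the only fixed effect.
* `Z` — an incidence matrix of size (training records) x (all genotyped
  individuals). Individuals without records are still in `g`; their breeding
  values are estimated through their genomic covariances.
* `R` — diagonal, `R_ii = (1 - r2_i) / r2_i` with `r2_i` the DRP reliability.
  Reliabilities are capped at 0.999 (a single authority in
  `layergp.deregression.RELIABILITY_CAP`), so a "perfect" record keeps a
  small but positive residual variance instead of an infinite weight.

### REML

The restricted likelihood is profiled down to one dimension. Records are
whitened by `R^(-1/2)`; the whitened `Z G Z'` is eigendecomposed once
(`K = U L U'`); for any variance ratio `lambda = sigma2_e / sigma2_g` the GLS
mean, the residual quadratic form and the restricted log-likelihood are then
O(n) expressions in the rotated coordinates. `log lambda` is maximized by
bounded Brent search on [log 1e-6, log 1e6] with tolerance 1e-8; `sigma2_g`
follows in closed form from the profiled quadratic form. The approach is
exact (no EM/AI iteration) and costs one `n x n` eigendecomposition per fit,
comfortable at the n ≈ 10^3 scale this package targets.

An optimum at either bound of the search interval is flagged as a boundary
solution (`sigma2_g` effectively 0 at the upper bound, `sigma2_e` effectively
0 at the lower) and a warning is emitted; the components are still returned.
Non-PSD relationship matrices (beyond an eigenvalue tolerance of -1e-8
relative) are rejected with the advice to add a diagonal ridge; the scenario
runner uses a ridge of 1e-8 throughout, which perturbs DGV well below every
tolerance used in the tests.

### Solving and backsolving

At fixed components the solver uses the covariance form

    g_hat = G Z' (Z G Z' + lambda R)^(-1) (y - X mu_hat)

rather than the G-inverse mixed-model equations, so singular G (a genuine
possibility for architecture matrices built from a handful of SNPs) is
handled without special cases, and validation individuals get DGV by
construction. The dual RRBLUP parameterization `g = M beta`,
`Var(beta_k) = w_k sigma2_g / c` gives the backsolved SNP effects

    beta_hat_k = (w_k / c) m_k' (Z G Z' + lambda R)^(-1) (y - X mu_hat)

which reproduce `M beta_hat = g_hat` exactly; the test suite enforces
agreement to 1e-6 for identity, -log10 P and squared-effect weights.

## Relationship matrices

`G = M D M' / c` with `c = 2 sum p_i (1 - p_i)`. Centering frequencies are
always those of the current (full, post-QC) panel — including in every
cross-validation fold — while all *weights* (GWAS p-values, RRBLUP effects,
blend parameters) are derived exclusively from the training fold. This split
mirrors how the matrices are defined: the relationship scale is a property of
the dataset, the trait-specific weighting is a property of the training data.

Weight vectors are divided by their mean, making every weighted matrix
scale-compatible with the identity-weight matrix; weighting is therefore
invariant to rescaling the raw weights. GWAS p-values are floored at 1e-300
before taking -log10 (an exact zero would otherwise be an infinite weight).

The architecture matrix `S` of the blend `G_z = omega S + (1 - omega) G_I`
selects `ceil(top% * m)` SNPs by absolute RRBLUP effect (ties broken by
ascending SNP index, making builds deterministic), weights them by squared
effect normalized *within the subset*, and uses the subset's own
`2 sum p(1-p)` denominator so S sits on the same expectation scale as `G_I`
before blending. Within-subset normalization was an open choice (against
normalizing by the full-panel mean); it is what keeps `omega` interpretable
as a pure mixing proportion. `(top%, omega)` are chosen by grid search —
default grids {0.05, 0.1, 0.5, 1, 2, 5, 10} x {0.1, ..., 0.9, 0.99} — scored
by inner cross-validation (inner k = 5, seeded from the outer fold) entirely
inside the training fold; exact ties break toward smaller omega, then smaller
top%.

## QC and annotation

Individuals are filtered first (call rate >= 0.95), SNP statistics are then
recomputed on the retained cohort, and SNPs are removed for MAF < 0.005,
call rate < 0.97, imputation Rsq < 0.8 (skipped when no Rsq is present), or
monomorphism (a monomorphic SNP contributes nothing to the G denominator).
All cuts are strict at the boundary. Each SNP receives exactly one of nine
annotation categories; when intervals of several classes overlap a position
the winner follows the precedence exon > splicing > ncRNA > UTR5 > UTR3 >
intron > upstream > downstream, and the genic flag (anything but intergenic)
is unaffected by the precedence. Gene bodies read from BED/GFF3 without finer
structure are treated as intronic and flanked by 1 kb upstream/downstream
intervals (the conventional default for gene-based SNP annotation).

## GWAS and PC selection

The association scan is ordinary least squares of the DRP on
[1, selected PCs, SNP dosage], one SNP at a time, with a two-sided t-test on
the dosage coefficient (residual df = n - #PCs - 2). The regression is
unweighted by default (reliability weighting inside the GWAS is available but
off, since the weights feed a ranking, not an inference). PCA standardizes
columns by `sqrt(2p(1-p))`, removes the individual mean, and eigendecomposes
the n x n Gram matrix. PCs are retained while their successive eigenvalues
are Tracy-Widom significant (each test conditioning on removal of the
previous PCs), so the selection is always a prefix of the eigenvalue order.

The Tracy-Widom (beta = 1) distribution is computed from the Hastings-McLeod
solution of Painleve II, integrated once with Airy-function initial data and
tabulated on a dense grid; beyond s = 6 the right-tail expansion
`log SF ~ -(2/3) s^(3/2) - (3/4) log s - log(4 sqrt(pi))` takes over, so the
1e-100 PC threshold is numerically meaningful. The tabulated distribution
reproduces the published 0.05 / 0.01 / 0.001 significance points (0.9793,
2.0234, 3.2724) to three digits. The effective marker count uses the moment
estimator from the eigenvalue dispersion with the sample count (one more than
the number of informative eigenvalues after centering); under a simulated
panmictic null this calibration gives a leading-eigenvalue false-positive
rate at or below the nominal 5%.

## De-regression

With `lambda = (1 - h2)/h2`, the information contents of the parent-average
and the individual's own sources solve the prediction-error-variance
identities

    lambda (Z'Z_i  + 2 lambda) / det = 0.5 - r2_PA
    lambda (Z'Z_PA + 4 lambda) / det = 1   - r2_EBV

whose closed form is implemented and cross-checked in the tests against a
numeric solve of the same system. The de-regressed proof is the individual's
equation solved for its record, `DRP = (-2 lambda PA + (Z'Z_i + 2 lambda)
EBV) / Z'Z_i`, with reliability `Z'Z_i / (Z'Z_i + lambda)`. Unknown parents
contribute EBV 0 (the population base) with reliability 0. Note that the
pedigree coupling term (-2 lambda) does *not* vanish as `r2_PA -> 0`, so the
method does not reduce to the simple `EBV / r2` de-regression in that limit;
`method="simple"` exists as a transparent fallback and as the shortcut used
by the synthetic direct-DRP mode. The trait heritability used for
de-regression is a required user input — there is no defensible default.

## The synthetic population

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Pedigree** — discrete generations; each generation draws sire/dam pairs
  from the previous one and every pair produces a fixed number of full sibs.
  Defaults (150 founders, 6 generations, 25 matings x 6 offspring) give a
  ~900-bird closed line; the ranking experiments configure 12-offspring
  families.
* **Founder LD** — haplotypes from a Gaussian-copula Markov chain: a latent
  AR(1) process with adjacent-pair correlation `exp(-d / d0)` (d0 = 100 kb
  by default) thresholded to per-locus target frequencies drawn
  Uniform(0.05, 0.5). This produces LD decaying with physical distance
  without a coalescent dependency — a deliberate simplification.
* **Meiosis** — gene dropping with a Poisson number of crossovers per
  1-Morgan chromosome, uniform crossover positions.
* **Annotation** — chromosomes tiled with genes (UTRs, alternating
  exons/introns, 2-bp splice sites, 1-kb flanks; every tenth gene an ncRNA)
  sized so gene territories hold the configured fraction (default one half)
  of SNPs.
* **Traits** — a configurable number of QTL drawn from the SNPs (optionally
  with genic sampling-odds enrichment; infinity = genic only) with normal
  effects scaled by `1/sqrt(n_qtl)`: many loci of very small effect. TBV is
  the centered-genotype dot product with the effects; environmental noise is
  calibrated to the target h².
* **DRP** — the default `direct_drp` mode adds noise to TBV so that
  `corr(DRP, TBV)^2` equals the target reliability (0.6 by default). The
  `pedigree_ebv` route runs a full animal-model BLUP on simulated phenotypes
  (Henderson A-inverse, inbreeding ignored) and feeds the EBVs and their
  PEV-based reliabilities through the Garrick-style de-regression, exercising
  that module end to end.
* **Array/imputation emulation** — an "HD" panel as an evenly spaced subset
  of the "WGS" panel, and an "imputed" panel where genotypes are replaced by
  Hardy-Weinberg draws at a MAF-dependent error rate (default 0.30 below MAF
  0.05, 0.01 above), with per-SNP Rsq = squared correlation of true and
  corrupted dosages. This reproduces the empirical signature that low-MAF
  SNPs carry low imputation quality.

What passing tests on these data do **not** show: realism of coalescent
genealogies, selection, genotyping-platform ascertainment, multi-trait
genetic correlations, or sex-chromosome inheritance. Conclusions about the
*relative* behavior of matrix recipes under a known architecture transfer;
absolute predictive abilities do not.

## Study-scale evaluation defaults

The headline synthetic study (tests and `scripts/acceptance.py`) uses a
1000-bird, five-generation population with 20,000 SNPs on five chromosomes,
half of them genic, traits with 2000 QTL at h² = 0.4, DRP reliability 0.6,
and 5-fold x 5-replicate cross-validation — sizes chosen so the whole
experimental design (including the per-fold GWAS and RRBLUP weight
derivations) runs in minutes on a single CPU while leaving the qualitative
contrasts (genic vs all SNPs, weighted vs identity) clearly measurable.
REML parameter-recovery checks use 20 replicates of a 500-bird pedigree;
at that size the per-replicate REML sampling sd of h² is about 0.05, so
recovery is asserted on the mean (±0.03) and per run only at 3 sd.

## Known limitations

* Variance components are re-estimated per fold per scenario; there is no
  option to share them across scenarios as a fixed-ratio analysis would.
* The GWAS is a plain linear scan; a GRM-corrected (mixed-model) scan is out
  of scope, so -log10 P weights inherit whatever stratification the PC
  covariates fail to absorb.
* `R_ii` assumes DRP records are uncorrelated between individuals, which
  de-regression only approximately guarantees inside dense full-sib families.
* The pedigree BLUP used by the synthetic EBV route ignores inbreeding in
  the A-inverse; for the shallow synthetic pedigrees the error is negligible,
  but the routine should not be pointed at deep real pedigrees.
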