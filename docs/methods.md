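# Methods

## The model

`gma` partitions the variance of expected genotypic values at one or more
multi-allelic quantitative-trait loci (QTL) into additive, dominance and
epistatic genetic components, using a regression parameterization that can
be fitted by ordinary weighted least squares.

At a locus with alleles `A_1 … A_m` and phase-known genotypes `(A_i, A_j)`
(paternal allele first), define transmission indicators `z_Pi`, `z_Mj` and
their mean-corrected versions

    x_Pi = z_Pi − p^i ,   x_Mj = z_Mj − p_j ,

where `p^i`, `p_j` are the paternal and maternal allele frequencies.
Because exactly one indicator per side is 1, the `x` variables are linearly
dependent; dropping the baseline allele `A_m` gives a full-rank
parameterization

    E(G|g) = μ + Σ_i α*^i x_Pi + Σ_j α*_j x_Mj + Σ_ij δ*^i_j x_Pi x_Mj ,

with `i, j ≤ m−1`.  The coefficients are average allelic effects and
allelic interactions *relative to the baseline allele* (`α*^i = α^i − α^m`
etc.); fitted genotypic values and all variance components are invariant to
the baseline choice.

When phase is unknown, paternal and maternal alleles are assumed to share
frequencies and effects, and the phase-dependent terms merge into genotype
coding variables that are well defined on unordered pairs:

    w_i  = x_Pi + x_Mi            (additive)
    v_ii = x_Pi x_Mi              (dominance, homozygous pair)
    v_ij = x_Pi x_Mj + x_Pj x_Mi  (dominance, heterozygous pair, i < j)

For `L` loci, a full model takes all products of per-locus coding variables.
Terms sharing the same per-locus allele counts (and parental origins, when
phased) form one **genetic component** `C`; the package enumerates
`2^(2L) − 1` components for phased models and `3^L − 1` for unphased ones.
Variance components are population variances of the per-subject component
scores.

## Estimation

Allele frequencies are gene-counted (homozygote share plus half of each
heterozygote share; by parent for phased data).  Coding variables are then
treated as fixed covariates and the model is fitted by weighted least
squares through the pseudo-inverse; rank-deficient designs (unobserved
genotype classes) return the minimum-norm solution with the aliased columns
reported, never silently dropped.  Environmental covariates enter as
ordinary regression columns.  A saturated fit on a full-rank genotype-class
table reproduces the class means exactly, and its coefficients do not
depend on the class weights.

Two variance-component routes are implemented:

* **Empirical** — weighted population variances and pairwise covariances of
  the component scores.  Valid under arbitrary Hardy-Weinberg or linkage
  disequilibrium; the identity `V(E(G|g)) = Σ V + 2 Σ Cov` holds by
  construction for any weighting.  All moments use the population divisor
  (total weight, i.e. divisor *n*), not *n − 1*: the components are defined
  as population variances.
* **Closed-form under equilibrium** — one-locus Hardy-Weinberg formulas
  (e.g. unphased `V_A = 2Σ p_i α*_i² − 2(Σ p_i α*_i)²`) and, for multiple
  loci under linkage and gametic equilibrium, product-form contractions of
  the coefficient arrays against per-locus kernels
  `K[s,s'] = p_s 1{s=s'} − p_s p_s'`.  Under equilibrium every
  cross-component covariance is zero.

### Rounded published frequencies

Published genotype tables are often rounded so that frequencies sum to
slightly off 1 (the ACP1 fixture's classes sum to 0.9999).  The package
deliberately does **not** renormalize: frequencies are used as given (an
out-of-tolerance sum beyond ±0.01 is an error), and weighted moments divide
by the total weight.  The one-locus closed forms are computed as exact
moments of the coding variables under the normalized Hardy-Weinberg class
distribution built from the raw frequencies; this reduces algebraically to
the textbook formulas when frequencies sum to 1 and stays exactly equal to
the empirical Hardy-Weinberg-weighted path otherwise.  A consequence worth
knowing: cross-baseline coefficient identities are exact only when
frequencies sum to exactly 1 (with the ACP1 round-off they hold to ~3e-4).

## Uncertainty and model building

**Bootstrap.** `bootstrap_varcomp` resamples subjects with replacement and
repeats the entire pipeline — allele-frequency estimation included, since
estimated frequencies are themselves a source of variation — inside every
replicate.  Replicates that lose an allele entirely (monomorphic locus,
singular full design) are skipped and counted.  Percentile intervals and
bootstrap SEs are reported; everything is deterministic given the seed.

**Existence tests.** A variance component is nonnegative, so its true value
under "no effect" sits on the boundary of the parameter space.  A
percentile CI of case-resampled estimates then cannot calibrate a test of
`V = 0`: every resampled estimate is positive and "CI excludes 0" rejects
essentially always (measured ~100% under a simulated null), while
basic/shifted intervals are far too conservative (~0.5%).  The package
therefore separates the two roles: `BootstrapResult.existence(eps)` keeps
the CI-excludes-neighborhood convention for descriptive screening (with the
neighborhood size an explicit, caller-chosen effect threshold), and
`component_existence_test` provides the calibrated test — a null-imposed
residual bootstrap in which the model *without* the component generates
bootstrap responses (fitted values plus resampled residuals, genotypes and
design held fixed) and the observed component variance is ranked against
its null distribution.  Measured type-I error: 3% at nominal 5% (200
simulated null datasets, n = 500, B = 200), with power 1.0 at a modest
additive effect (α = 0.4, residual SD 1).

**Forward selection.** Reduced models are built at whole-component
granularity (terms of one component are mutually correlated and enter or
leave together).  Candidates are scanned by ascending order; within the
lowest order containing a qualifying candidate, the largest
likelihood-ratio improvement enters if its p-value is below the entry
level.  The LR statistic uses the Gaussian working likelihood
`n·log(RSS0/RSS1)` with χ² reference, df = rank added (the reference
distribution is a convention; the working likelihood is exact only for
Gaussian residuals).  Because the coding variables are mean-corrected, the
components are uncorrelated in equilibrium populations and the low-order
scan is not confounded by absent higher-order terms — the F-infinity coding
(raw allele counts and genotype indicators, available via
`f_infinity_design` for contrast) lacks this property.  An optional
backward pass (`allow_drop=True`) is off by default.  Ties among same-order
candidates break by largest LR, then canonical component order.

## The synthetic-data generator

`PopulationModel` draws one paternal and one maternal gamete per subject,
independently (gametic equilibrium and HWE), each from its parent's gamete
table — by default the product of per-locus allele frequencies (linkage
equilibrium).  Supplying an explicit gamete table induces LD; supplying an
explicit joint genotype-class distribution induces arbitrary HWD exactly,
which is how a published genotype-frequency table is emulated
(`PopulationModel.from_class_table`).  HWD is specified through class
frequencies rather than an inbreeding coefficient because the estimators'
behavior under HWD is driven by the full covariance pattern of the index
variables, not a single summary.  Phenotypes are
`y = E(G|g) + N(0, σ²)`; residuals are Gaussian only — the least-squares
theory needs only i.i.d. residuals, and Gaussian is the simplest concrete
choice.  What the generator does *not* emulate: genotyping error, missing
data mechanisms, population structure/admixture, linked pedigrees, or
non-Gaussian trait distributions — passing recovery tests here says nothing
about robustness to those features of real data.

## Numerical choices and problem sizes

* Deterministic column order: intercept, then components by ascending
  order and loci left-to-right; within a dominance component, homozygous
  pairs precede heterozygous pairs (matching the usual display of the
  three-allele saturated matrix).
* Allele-frequency maps must sum to 1 within ±0.01 (rounded published
  tables pass, with a logged warning); frequencies are never renormalized.
* Degenerate inputs: a single genotype class yields all-zero variance
  components with a warning; all-missing loci and unphased input to
  phase-known analyses are hard errors.
* Test-suite problem sizes were chosen so the whole suite runs in a few
  minutes on one core: recovery curves use n ∈ {500, 5000, 50000}; the
  null calibration of the existence test uses 200 simulated datasets with
  B = 200; Hardy-Weinberg convergence checks use n = 10⁵.

## Known limitations

* Analytic variance/covariance formulas under Hardy-Weinberg or linkage
  *disequilibrium* are not implemented; the empirical path (exact for any
  weighting) covers those populations.
* The multi-locus closed forms assume per-locus frequencies summing to 1;
  with rounded published frequencies use the empirical path.
* No mixed models, REML/GLS, genotype-by-environment interaction, VCF
  parsing, phasing or imputation; missing genotypes are excluded, not
  modeled as an extra allele.
* `cov(β̂)` treating allele frequencies as random is not implemented; the
  bootstrap covers frequency-estimation uncertainty.
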