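# gma — general multi-allele models for quantitative-trait loci

`gma` estimates **average allelic effects and interactions** and partitions
the genotypic variance of a quantitative trait into **additive, dominance
and epistatic components** at multi-allelic QTL — with phase-known or
phase-unknown genotypes, one or many loci, in Hardy-Weinberg/linkage
equilibrium or not.  It is aimed at quantitative and statistical
geneticists who want Fisher-style variance components but fitted with
ordinary least squares, without the redundant-parameter constraints of the
classical ANOVA formulation.

## The model in brief

For a locus with alleles `A_1 … A_m`, transmission indicators are
mean-corrected (`x_Pi = z_Pi − p^i`) and the baseline allele `A_m` is
dropped, giving a full-rank regression for the expected genotypic values:

    E(G|g) = μ + Σ α*^i x_Pi + Σ α*_j x_Mj + Σ δ*^i_j x_Pi x_Mj

With unknown phase the terms merge into genotype coding variables
`w_i = x_Pi + x_Mi` and `v_ij = x_Pi x_Mj + x_Pj x_Mi`, which are well
defined on unordered allele pairs.  Multi-locus models take products of
per-locus coding variables; terms with the same per-locus allele counts
form one *genetic component* (`A(k)`, `D(k)`, `A(j)xA(k)`, …), and variance
components are population variances of the per-subject component sums.
Because the coding variables have mean zero, the components are mutually
orthogonal in equilibrium populations; in disequilibrium the empirical
path reports their covariances explicitly.  See `docs/methods.md` for the
full account.

## Worked example: the ACP1 polymorphism

The package ships the published three-allele human acid phosphatase (ACP1)
genotype-class table (alleles A, B, C; traits: enzyme activity and
inhibition).

```python
from gma import GMAModel, hwe_weights, load_acp1

table, locus = load_acp1()            # frequencies gene-counted: A 0.3534,
                                      # B 0.5818, C 0.0647 (baseline C)
res = GMAModel.from_class_table(table, [locus], "activity").fit()
print(res.summary())
print(res.varcomp().summary())
```

```
GMA model fit
==============================================
rows: 6   columns: 6   phase: unknown
sigma2 (residual): 1.05808e-26
----------------------------------------------
term                              estimate
mu                                 167.735
a(acp1=A)                         -59.2599
a(acp1=B)                         -26.2541
d(acp1=A,A)                           -4.8
d(acp1=B,B)                            3.7
d(acp1=A,B)                             -2

Genetic variance components (empirical)
----------------------------------------------------
component                     variance       share
A(acp1)                        658.868      99.96%
D(acp1)                       0.973318       0.15%
Cov(A(acp1),D(acp1))      -0.356258
V(E(G|g)) total                659.129
```

Reading: the saturated six-parameter fit reproduces the six expected
genotypic values exactly (residual variance is numerically zero), the A
allele lowers activity by ~59 units relative to baseline C, and almost all
genotypic variance (99.96%) is additive.  The nonzero `Cov(A, D)` is the
footprint of the slight Hardy-Weinberg disequilibrium in the observed
genotype frequencies; replacing the class weights with Hardy-Weinberg
products (`res.varcomp(weights=hwe_weights(table.genotypes, [locus]))`)
gives the equilibrium partition `V_A = 660.588`, `V_D = 0.971` with a
covariance near zero.  For the inhibition trait the observed-frequency
additive share is 100.65% — above 100%, because under disequilibrium
`V_D + 2 Cov(A, D)` can be negative.

Beyond this example the library provides phased models (separate paternal
and maternal effects), multi-locus epistatic components, closed-form
equilibrium variance components, subject-level fits with covariates,
bootstrap confidence intervals and existence tests
(`gma.inference`), hierarchical forward selection of components, and a
seed-deterministic genotype/phenotype simulator (`gma.PopulationModel`)
supporting LD and exact Hardy-Weinberg disequilibrium.

A thin CLI mirrors the library:

```bash
gma simulate --model model.yaml --n 1000 --seed 1 --out subjects.tsv
gma fit      --model model.yaml --genotypes subjects.tsv --trait y --out fit.json
gma varcomp  --model model.yaml --genotypes subjects.tsv --trait y \
             --weights hwe --out vc.json
```

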