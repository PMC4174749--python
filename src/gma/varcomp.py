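"""Genetic variance and covariance components.

Two routes are provided:

* :func:`varcomp_empirical` — weighted population variances/covariances of
  the fitted per-row component scores.  Valid under arbitrary Hardy-Weinberg
  or linkage disequilibrium: the decomposition
  ``V(E(G|g)) = sum(V) + 2*sum(Cov)`` holds for any weighting, with the
  cross-component covariances absorbing the disequilibrium.
* closed forms under equilibrium — :func:`varcomp_hwe_one_locus_unphased`,
  :func:`varcomp_hwe_one_locus_phased` and the multi-locus
  :func:`varcomp_equilibrium_multilocus`, where every cross-component
  covariance is zero and each component variance is a product-form
  contraction of the coefficient arrays against per-locus frequency kernels
  ``K[s, s'] = p_s 1{s = s'} - p_s p_s'``.

All moments use the population divisor (total weight, i.e. divisor ``n``
for unit weights), matching the definition of the components as population
variances rather than unbiased sample estimators.

The one-locus closed forms are computed as exact moments of the coding
variables under the normalized Hardy-Weinberg class distribution built from
the locus's (possibly rounded, hence not exactly summing to 1) allele
frequencies.  When the frequencies do sum to 1 this reduces algebraically to
the familiar textbook expressions, e.g. unphased
``V_A = 2*sum_i p_i a_i**2 - 2*(sum_i p_i a_i)**2``; with rounded published
frequencies it remains exactly equal to the empirical path run with
Hardy-Weinberg class weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import Genotype, LocusSpec
from .design import ComponentKey, DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarCompResult",
    "varcomp_empirical",
    "varcomp_hwe_one_locus_unphased",
    "varcomp_hwe_one_locus_phased",
    "varcomp_equilibrium_multilocus",
    "hwe_weights",
]


@dataclass
class VarCompResult:
    """Variances of each genetic component, their pairwise covariances and
    the total variance of the expected genotypic values.

    ``total`` is ``sum(variances) + 2*sum(covariances)`` by construction, so
    the decomposition identity holds exactly.  ``ratios`` are each variance
    over the total (the additive ratio can exceed 1 when the dominance-plus-
    covariance remainder is negative, as happens under Hardy-Weinberg
    disequilibrium)."""

    variances: dict[str, float]
    covariances: dict[tuple[str, str], float]
    total: float
    method: str                      # "empirical" | "analytic"
    equilibrium: bool
    grand_mean: float = 0.0          # weighted mean of the summed scores

    @property
    def ratios(self) -> dict[str, float]:
        if self.total == 0:
            return {k: float("nan") for k in self.variances}
        return {k: v / self.total for k, v in self.variances.items()}

    def variance(self, name: str) -> float:
        return self.variances[name]

    def covariance(self, a: str, b: str) -> float:
        if (a, b) in self.covariances:
            return self.covariances[(a, b)]
        return self.covariances[(b, a)]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "equilibrium": self.equilibrium,
            "total": self.total,
            "grand_mean": self.grand_mean,
            "variances": dict(self.variances),
            "covariances": {f"{a},{b}": v
                            for (a, b), v in self.covariances.items()},
            "ratios": self.ratios,
        }

    def summary(self) -> str:
        lines = ["Genetic variance components "
                 f"({self.method}{', equilibrium' if self.equilibrium else ''})",
                 "-" * 52,
                 f"{'component':<24}{'variance':>14}{'share':>12}"]
        for k, v in self.variances.items():
            r = self.ratios[k]
            lines.append(f"{k:<24}{v:>14.6g}{100 * r:>11.2f}%")
        for (a, b), c in self.covariances.items():
            lines.append(f"Cov({a},{b}){'':<{max(0, 15 - len(a) - len(b))}}"
                         f"{c:>14.6g}")
        lines.append(f"{'V(E(G|g)) total':<24}{self.total:>14.6g}")
        return "\n".join(lines)


def varcomp_empirical(scores: pd.DataFrame, weights) -> VarCompResult:
    """Weighted population variances/covariances of component scores.

    Parameters
    ----------
    scores : DataFrame
        One column per genetic component (from
        :meth:`gma.model.GMAResults.component_scores`).
    weights : array-like
        Row weights (subject weights or genotype-class frequencies); they
        are used as relative weights, i.e. moments divide by the total
        weight.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    if len(w) != len(scores):
        raise ValueError("weights length mismatch")
    if len(scores) < 2:
        logger.warning("single row: all variance components are zero")
    W = w / w.sum()
    S = scores.to_numpy(dtype=float)
    means = W @ S
    Sc = S - means
    C = (Sc * W[:, None]).T @ Sc
    names = list(scores.columns)
    variances = {nm: float(C[k, k]) for k, nm in enumerate(names)}
    covariances = {(names[a], names[b]): float(C[a, b])
                   for a in range(len(names)) for b in range(a + 1, len(names))}
    total = sum(variances.values()) + 2.0 * sum(covariances.values())
    return VarCompResult(variances, covariances, total, method="empirical",
                         equilibrium=False, grand_mean=float(means.sum()))


# ---------------------------------------------------------------------------
# Hardy-Weinberg class weights
# ---------------------------------------------------------------------------

def hwe_weights(genotypes: pd.DataFrame, loci: Sequence[LocusSpec],
                phased: bool = False) -> np.ndarray:
    """Per-row Hardy-Weinberg (x linkage-equilibrium) class weights.

    Unphased rows get ``prod_k p_i p_j * (2 if heterozygous)``, phased rows
    ``prod_k p^P_i p^M_j``, built from each locus's allele frequencies as
    given (no renormalization: with rounded frequencies the weights sum to
    the squared round-off, and downstream moments divide by that sum)."""
    out = np.ones(len(genotypes))
    for loc in loci:
        for r, tok in enumerate(genotypes[loc.locus_id]):
            g = Genotype.from_token(tok)
            if phased:
                out[r] *= loc.p_pat[loc.index(g.a1)] * loc.p_mat[loc.index(g.a2)]
            else:
                p1, p2 = loc.p[loc.index(g.a1)], loc.p[loc.index(g.a2)]
                out[r] *= p1 * p2 * (2.0 if g.a1 != g.a2 else 1.0)
    return out


# ---------------------------------------------------------------------------
# one-locus closed forms
# ---------------------------------------------------------------------------

def _one_locus_params(fit, locus: LocusSpec, phased: bool):
    """Extract the additive vector(s) and the dominance coefficient matrix
    over non-baseline alleles from a one-locus fit."""
    design: DesignMatrix = fit.design
    if len(design.loci) != 1:
        raise ValueError("one-locus closed form on a multi-locus fit")
    if design.phased != phased:
        raise ValueError("fit phase flag mismatch")
    nb = locus.nonbaseline
    r = len(nb)
    beta = fit.genetic_params
    if phased:
        aP = np.zeros(r)
        aM = np.zeros(r)
        D = np.zeros((r, r))
        for k, lab in enumerate(design.labels):
            if lab.is_intercept:
                continue
            (i, j), al = lab.component.key[0], lab.alleles[0]
            if (i, j) == (1, 0):
                aP[nb.index(al[0])] = beta[k]
            elif (i, j) == (0, 1):
                aM[nb.index(al[1])] = beta[k]
            else:
                D[nb.index(al[0]), nb.index(al[1])] = beta[k]
        return aP, aM, D
    alpha = np.zeros(r)
    D = np.zeros((r, r))
    for k, lab in enumerate(design.labels):
        if lab.is_intercept:
            continue
        e, al = lab.component.key[0], lab.alleles[0]
        if e == 1:
            alpha[nb.index(al[0])] = beta[k]
        elif e == 2:
            s, t = nb.index(al[0]), nb.index(al[1])
            D[s, t] = D[t, s] = beta[k]
    return alpha, D


def _x_vectors(locus: LocusSpec, p: np.ndarray):
    """Rows: for each allele i, the vector of mean-corrected indicators over
    the non-baseline coordinates, built with the raw frequencies ``p``."""
    sel = [locus.index(a) for a in locus.nonbaseline]
    m = locus.m
    xv = np.tile(-p[sel], (m, 1))
    for i, a in enumerate(locus.alleles):
        if a in locus.nonbaseline:
            xv[i, locus.nonbaseline.index(a)] += 1.0
    return xv


def varcomp_hwe_one_locus_unphased(fit, locus: LocusSpec | None = None):
    """Closed-form ``(V_A, V_D)`` of a one-locus phase-unknown fit under
    Hardy-Weinberg equilibrium.

    Equals the empirical path run with Hardy-Weinberg class weights to
    machine precision, for any allele frequencies (including rounded ones
    that do not sum exactly to 1)."""
    locus = locus or fit.design.loci[0]
    alpha, D = _one_locus_params(fit, locus, phased=False)
    p = locus.p
    q = p / p.sum()
    abar = np.zeros(locus.m)
    for k, a in enumerate(locus.nonbaseline):
        abar[locus.index(a)] = alpha[k]
    V_A = 2.0 * float(q @ abar ** 2 - (q @ abar) ** 2)
    xv = _x_vectors(locus, p)
    mu = q @ xv
    M2 = np.einsum("i,is,it->st", q, xv, xv)
    V_D = float(np.trace(D @ M2 @ D @ M2) - (mu @ D @ mu) ** 2)
    return V_A, V_D


def varcomp_hwe_one_locus_phased(fit, locus: LocusSpec | None = None):
    """Closed-form ``(V_AP, V_AM, V_D)`` of a one-locus phase-known fit
    under Hardy-Weinberg equilibrium (independent paternal and maternal
    draws, possibly with different gamete frequencies)."""
    locus = locus or fit.design.loci[0]
    aP, aM, D = _one_locus_params(fit, locus, phased=True)
    out = []
    margins = []
    for a, p in ((aP, locus.p_pat), (aM, locus.p_mat)):
        q = p / p.sum()
        abar = np.zeros(locus.m)
        for k, al in enumerate(locus.nonbaseline):
            abar[locus.index(al)] = a[k]
        out.append(float(q @ abar ** 2 - (q @ abar) ** 2))
        xv = _x_vectors(locus, p)
        margins.append((q @ xv, np.einsum("i,is,it->st", q, xv, xv)))
    (muP, M2P), (muM, M2M) = margins
    V_D = float(np.trace(D @ M2M @ D.T @ M2P) - (muP @ D @ muM) ** 2)
    return out[0], out[1], V_D


# ---------------------------------------------------------------------------
# multi-locus equilibrium product forms
# ---------------------------------------------------------------------------

def _kernel(p_nb: np.ndarray) -> np.ndarray:
    return np.diag(p_nb) - np.outer(p_nb, p_nb)


def _component_variance_equilibrium(fit, key: ComponentKey) -> float:
    """Product-form variance of one component.

    The coefficient array is laid out as a tensor with one axis per involved
    single-allele slot (loci left-to-right; per locus, paternal before
    maternal for phased models, the two dominance slots otherwise).  Each
    within-locus dominance coefficient is placed at both orderings of its
    allele pair (the symmetric extension delta[t, s] = delta[s, t]).  The
    variance is then ``t' (kron of kernels) t`` with kernel
    ``K = diag(p) - p p'`` over non-baseline alleles, doubled for unphased
    additive slots (two alleles contribute one ``w`` each)."""
    design: DesignMatrix = fit.design
    loci = design.loci
    beta = fit.genetic_params
    dims: list[int] = []
    kernels: list[np.ndarray] = []
    for loc, e in zip(loci, key.key):
        nb = [loc.index(a) for a in loc.nonbaseline]
        r = len(nb)
        if design.phased:
            i, j = e
            if i:
                dims.append(r)
                kernels.append(_kernel(loc.p_pat[nb]))
            if j:
                dims.append(r)
                kernels.append(_kernel(loc.p_mat[nb]))
        else:
            p = loc.p[nb]
            if e == 1:
                dims.append(r)
                kernels.append(2.0 * _kernel(p))
            elif e == 2:
                dims.extend([r, r])
                kernels.extend([_kernel(p), _kernel(p)])
    T = np.zeros(dims)
    for col in design.columns_of(key):
        lab = design.labels[col]
        per_locus: list[list[tuple[int, ...]]] = []
        for k, (loc, e) in enumerate(zip(loci, key.key)):
            nb = loc.nonbaseline
            al = lab.alleles[k]
            if design.phased:
                i, j = e
                part: list[int] = []
                if i:
                    part.append(nb.index(al[0]))
                if j:
                    part.append(nb.index(al[1]))
                if part:
                    per_locus.append([tuple(part)])
            elif e == 1:
                per_locus.append([(nb.index(al[0]),)])
            elif e == 2:
                s, t = nb.index(al[0]), nb.index(al[1])
                per_locus.append([(s, t)] if s == t else [(s, t), (t, s)])
        for combo in itertools.product(*per_locus):
            idx = tuple(x for part in combo for x in part)
            T[idx] += beta[col]
    t = T.reshape(-1)
    M = reduce(np.kron, kernels)
    return float(t @ M @ t)


def varcomp_equilibrium_multilocus(fit, loci=None) -> VarCompResult:
    """Analytic variance components under gametic and linkage equilibrium.

    Each component's variance is the product-form contraction of its
    coefficient array against the per-locus frequency kernels; all
    cross-component covariances are zero, so the total is simply the sum.
    The caller asserts equilibrium — in disequilibrium use the empirical
    path instead.  Assumes each locus's frequencies sum to 1."""
    design: DesignMatrix = fit.design
    names = [key.name(design.loci) for key in design.components]
    variances = {}
    for key, nm in zip(design.components, names):
        variances[nm] = _component_variance_equilibrium(fit, key)
    covariances = {(names[a], names[b]): 0.0
                   for a in range(len(names)) for b in range(a + 1, len(names))}
    total = sum(variances.values())
    return VarCompResult(variances, covariances, total, method="analytic",
                         equilibrium=True, grand_mean=0.0)
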