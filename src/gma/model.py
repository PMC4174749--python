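"""Least-squares fitting of GMA models, statsmodels-style.

:class:`GMAModel` wraps a response vector, a :class:`~gma.design.DesignMatrix`
and optional environmental covariates; :meth:`GMAModel.fit` performs weighted
least squares via the pseudo-inverse and returns :class:`GMAResults`, which
carries the labeled coefficient estimates, per-subject genetic component
scores and the empirical variance-component machinery.

Because the coding variables are treated as fixed covariates, a saturated
(full) model on a full-rank genotype-class table reproduces the expected
genotypic values exactly, and its coefficients do not depend on the class
weights — they are determined by the allele frequencies and the class means
alone.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .coding import ClassTable, Genotype, LocusSpec, estimate_allele_freqs
from .design import ComponentKey, DesignMatrix, build_design

logger = logging.getLogger(__name__)

__all__ = ["GMAModel", "GMAResults", "fit_ls", "genetic_component_scores"]


def _drop_missing(table: pd.DataFrame, loci: Sequence[LocusSpec]
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    ids = [l.locus_id for l in loci]
    mask = np.ones(len(table), dtype=bool)
    for lid in ids:
        col = table[lid]
        mask &= [not Genotype.from_token(t).token() == "." for t in col]
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d rows with missing genotypes", dropped)
    return table.loc[mask].reset_index(drop=True), mask


class GMAModel:
    """A GMA regression model for one quantitative trait.

    Parameters
    ----------
    endog : array-like
        Response (trait values per subject, or expected genotypic values
        per class).
    design : DesignMatrix
        Genetic design from :func:`gma.design.build_design`.
    exog_covariates : 2d array-like, optional
        Environmental covariates with fixed effects, appended after the
        genetic columns.
    covariate_names : sequence of str, optional
    weights : array-like, optional
        Row weights; defaults to the design's weights (1 per subject, class
        frequency per class row).
    """

    def __init__(self, endog, design: DesignMatrix, exog_covariates=None,
                 covariate_names=None, weights=None):
        self.endog = np.asarray(endog, dtype=float)
        self.design = design
        if self.endog.shape[0] != design.n_rows:
            raise ValueError("endog and design row counts differ")
        if exog_covariates is None:
            self.exog_covariates = np.empty((design.n_rows, 0))
            self.covariate_names = []
        else:
            self.exog_covariates = np.atleast_2d(
                np.asarray(exog_covariates, dtype=float))
            if self.exog_covariates.shape[0] != design.n_rows:
                self.exog_covariates = self.exog_covariates.T
            if self.exog_covariates.shape[0] != design.n_rows:
                raise ValueError("covariate row count mismatch")
            ncov = self.exog_covariates.shape[1]
            self.covariate_names = list(covariate_names or
                                        [f"cov{k}" for k in range(ncov)])
        self.weights = (np.asarray(weights, dtype=float)
                        if weights is not None else design.weights.copy())
        if (self.weights < 0).any() or self.weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")

    # ------------------------------------------------------------------
    @classmethod
    def from_subject_table(cls, table: pd.DataFrame, loci: Sequence[LocusSpec],
                           trait: str, covariates: Sequence[str] = (),
                           components="full", phased: bool = False,
                           estimate_freqs: bool | str = "auto") -> "GMAModel":
        """Build a model from a subject-level table of genotype tokens.

        Rows with a missing genotype at any modeled locus are excluded.
        When ``estimate_freqs`` is true (or ``"auto"`` and a locus carries no
        frequencies), allele frequencies are gene-counted from the retained
        rows (by-parent for phased models, pooled otherwise).
        """
        table = pd.DataFrame(table)
        if trait not in table.columns:
            raise KeyError(f"unknown trait column {trait!r}")
        for c in covariates:
            if c not in table.columns:
                raise KeyError(f"unknown covariate column {c!r}")
        table, _ = _drop_missing(table, loci)
        loci = list(loci)
        for k, loc in enumerate(loci):
            need = (estimate_freqs is True or
                    (estimate_freqs == "auto" and not loc.has_freqs))
            if need:
                if phased:
                    pat, mat = estimate_allele_freqs(
                        table[loc.locus_id], loc, mode="by-parent")
                    loci[k] = loc.with_freqs(paternal=pat, maternal=mat)
                else:
                    p = estimate_allele_freqs(table[loc.locus_id], loc,
                                              mode="pooled")
                    loci[k] = loc.with_freqs(pooled=p)
        design = build_design(table[[l.locus_id for l in loci]], loci,
                              components=components, phased=phased)
        exog = table[list(covariates)].to_numpy(dtype=float) if covariates else None
        return cls(table[trait].to_numpy(dtype=float), design,
                   exog_covariates=exog, covariate_names=list(covariates))

    @classmethod
    def from_class_table(cls, table: ClassTable, loci: Sequence[LocusSpec],
                         trait: str, components="full",
                         weights="observed") -> "GMAModel":
        """Build a (phase-unknown) model from a genotype-class table.

        ``weights="observed"`` uses the table's class frequencies;
        ``weights="hwe"`` replaces them with Hardy-Weinberg products of the
        loci's allele frequencies.  For a saturated full-rank table the
        coefficient estimates are identical either way.  Loci without
        frequencies get them gene-counted from the class table, using the
        class frequencies as weights (published round-off preserved).
        """
        loci = list(loci)
        for k, loc in enumerate(loci):
            if not loc.has_freqs:
                p = estimate_allele_freqs(table.genotypes[loc.locus_id], loc,
                                          weights=table.frequency)
                loci[k] = loc.with_freqs(pooled=p)
        design = build_design(table, loci, components=components, phased=False)
        y = table.trait(trait)
        if isinstance(weights, str):
            if weights == "observed":
                w = design.weights
            elif weights == "hwe":
                from .varcomp import hwe_weights
                w = hwe_weights(design.genotypes, loci)
            else:
                raise ValueError(f"unknown weights mode {weights!r}")
        else:
            w = np.asarray(weights, dtype=float)
        return cls(y, design, weights=w)

    # ------------------------------------------------------------------
    def fit(self) -> "GMAResults":
        """Weighted least squares via the Moore-Penrose pseudo-inverse.

        Minimizes ``sum_k w_k (y_k - x_k' beta)**2``.  When the design is
        rank deficient (e.g. unobserved genotype classes) the minimum-norm
        solution is returned and the inestimable (aliased) columns are
        reported in ``GMAResults.aliased`` with a logged warning — they are
        not silently dropped."""
        X = np.column_stack([self.design.X, self.exog_covariates])
        sw = np.sqrt(self.weights)
        keep = sw > 0
        Xw = X[keep] * sw[keep, None]
        yw = self.endog[keep] * sw[keep]
        params, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rank = np.linalg.matrix_rank(Xw)
        aliased: list[str] = []
        if rank < X.shape[1]:
            # QR with column pivoting flags the dependent columns
            _, _, piv = linalg.qr(Xw, mode="economic", pivoting=True)
            names = self.param_names
            aliased = sorted(names[k] for k in piv[rank:])
            logger.warning("rank-deficient design: %d aliased column(s): %s",
                           len(aliased), ", ".join(aliased))
        fitted = X @ params
        return GMAResults(self, params, fitted, aliased)

    @property
    def param_names(self) -> list[str]:
        return self.design.column_names + self.covariate_names


class GMAResults:
    """Fit results: labeled coefficients, component scores, diagnostics."""

    def __init__(self, model: GMAModel, params: np.ndarray,
                 fittedvalues: np.ndarray, aliased: list[str]):
        self.model = model
        self._params = np.asarray(params, dtype=float)
        self.fittedvalues = np.asarray(fittedvalues, dtype=float)
        self.aliased = aliased

    # -- coefficient access ---------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.param_names)

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    @property
    def mu(self) -> float:
        """Intercept: the order-0 genetic component."""
        return float(self._params[0])

    @property
    def genetic_params(self) -> np.ndarray:
        return self._params[: self.design.n_cols]

    @property
    def covariate_params(self) -> pd.Series:
        ncov = len(self.model.covariate_names)
        return pd.Series(self._params[self.design.n_cols:],
                         index=self.model.covariate_names)

    def coef(self, label) -> float:
        """Coefficient by EffectLabel or by column name."""
        if isinstance(label, str):
            return float(self.params[label])
        idx = self.design.labels.index(label)
        return float(self._params[idx])

    # -- diagnostics -----------------------------------------------------
    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rss(self) -> float:
        return float(self.model.weights @ self.resid ** 2)

    @property
    def sigma2(self) -> float:
        """Residual variance estimate (weighted RSS over total weight)."""
        return self.rss / float(self.model.weights.sum())

    @property
    def nobs(self) -> int:
        return int(self.design.n_rows)

    # -- genetic components ----------------------------------------------
    @property
    def fitted_genotypic_values(self) -> np.ndarray:
        """Fitted E(G|g) per row: genetic part only (covariates excluded)."""
        return self.design.X @ self.genetic_params

    def component_scores(self) -> pd.DataFrame:
        """Per-row score of every genetic component.

        Column ``name(C)`` holds the sum of that component's design columns
        times their coefficients.  The intercept plus all component scores
        reconstructs the fitted genotypic value exactly."""
        beta = self.genetic_params
        out = {}
        for key in self.design.components:
            cols = self.design.columns_of(key)
            out[key.name(self.design.loci)] = self.design.X[:, cols] @ beta[cols]
        return pd.DataFrame(out, index=range(self.nobs))

    def varcomp(self, weights=None):
        """Empirical genetic variance/covariance components.

        Weighted population (divisor = total weight) variances and pairwise
        covariances of the component scores; defaults to the fit weights.
        See :func:`gma.varcomp.varcomp_empirical`."""
        from .varcomp import varcomp_empirical
        w = self.model.weights if weights is None else weights
        return varcomp_empirical(self.component_scores(), w)

    # -- reporting ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "trait_intercept": self.mu,
            "params": {k: float(v) for k, v in self.params.items()},
            "sigma2": self.sigma2,
            "nobs": self.nobs,
            "aliased": list(self.aliased),
            "phased": self.design.phased,
            "loci": [
                {
                    "locus_id": l.locus_id,
                    "alleles": list(l.alleles),
                    "baseline": l.baseline,
                    "freq_paternal": list(l.freq_paternal or []),
                    "freq_maternal": list(l.freq_maternal or []),
                }
                for l in self.design.loci
            ],
        }
        return d

    def summary(self) -> str:
        lines = ["GMA model fit",
                 "=" * 46,
                 f"rows: {self.nobs}   columns: {len(self._params)}   "
                 f"phase: {'known' if self.design.phased else 'unknown'}",
                 f"sigma2 (residual): {self.sigma2:.6g}",
                 "-" * 46,
                 f"{'term':<28}{'estimate':>14}"]
        for name, val in self.params.items():
            flag = "  (aliased)" if name in self.aliased else ""
            lines.append(f"{name:<28}{val:>14.6g}{flag}")
        if self.aliased:
            lines.append(f"aliased columns: {len(self.aliased)}")
        return "\n".join(lines)


def fit_ls(design: DesignMatrix, y, weights=None) -> GMAResults:
    """Functional entry point: weighted LS fit of a design against ``y``."""
    return GMAModel(y, design, weights=weights).fit()


def genetic_component_scores(fit: GMAResults,
                             design: DesignMatrix | None = None) -> pd.DataFrame:
    """Per-row genetic component scores of a fit (see
    :meth:`GMAResults.component_scores`)."""
    if design is not None and design is not fit.design:
        raise ValueError("fit and design do not share metadata")
    return fit.component_scores()
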