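"""Uncertainty and model building for GMA variance components.

Variance components are nonlinear functions of the fitted coefficients and
of the allele frequencies, which are themselves estimated from the sample;
:func:`bootstrap_varcomp` therefore resamples whole subjects with
replacement and repeats the entire pipeline — frequency estimation, design
construction, least-squares fit, component scores, empirical components —
inside every replicate, so the frequency-estimation noise propagates into
the intervals.

:func:`forward_select` builds reduced models by hierarchical forward
selection over whole genetic components: starting from the intercept (plus
covariates), the candidate of the lowest order with a significant
likelihood-ratio improvement enters at each step.  Because GMA columns are
mean-corrected, the components are mutually orthogonal in equilibrium
populations and the low-order scan is not confounded by absent higher-order
terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding import LocusSpec
from .design import ComponentKey, build_design, enumerate_components
from .model import GMAModel

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "SelectionTrace", "bootstrap_varcomp",
           "component_existence_test", "forward_select"]


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the genetic variance/covariance components.

    ``point`` holds the full-sample estimates; ``replicates`` one row per
    successful replicate; ``ci`` percentile intervals at ``level``;
    ``se`` the bootstrap standard errors (undefined, hence None, when fewer
    than two replicates succeeded)."""

    point: pd.Series
    replicates: pd.DataFrame
    ci: pd.DataFrame
    se: pd.Series | None
    B: int
    n_skipped: int
    seed: int
    level: float

    def existence(self, eps: float = 0.0) -> pd.Series:
        """Existence test per quantity: True when the percentile CI excludes
        the neighborhood ``[-eps, eps]`` of zero.

        This is a pragmatic convention (the bootstrap has no canonical null
        for variance components, which are bounded below by 0); ``eps`` lets
        the caller demand a practically relevant effect size."""
        return (self.ci["lower"] > eps) | (self.ci["upper"] < -eps)

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "n_skipped": self.n_skipped,
            "seed": self.seed,
            "level": self.level,
            "point": {k: float(v) for k, v in self.point.items()},
            "se": (None if self.se is None
                   else {k: float(v) for k, v in self.se.items()}),
            "ci": {k: [float(self.ci.loc[k, "lower"]),
                       float(self.ci.loc[k, "upper"])]
                   for k in self.ci.index},
        }


def _varcomp_quantities(table: pd.DataFrame, loci, trait, covariates,
                        components, phased, weights_mode) -> pd.Series | None:
    """One full pipeline pass; None when a locus is monomorphic."""
    model = GMAModel.from_subject_table(
        table, loci, trait, covariates=covariates, components=components,
        phased=phased, estimate_freqs=True)
    for loc in model.design.loci:
        freqs = [loc.p_pat, loc.p_mat] if phased else [loc.p]
        if any((np.asarray(f) == 0).any() for f in freqs):
            return None
    res = model.fit()
    if weights_mode == "hwe":
        from .varcomp import hwe_weights
        w = hwe_weights(model.design.genotypes, model.design.loci, phased)
    else:
        w = None
    vc = res.varcomp(weights=w)
    out = {}
    for name, v in vc.variances.items():
        out[f"V({name})"] = v
    for (a, b), c in vc.covariances.items():
        out[f"Cov({a},{b})"] = c
    out["total"] = vc.total
    for name, r in vc.ratios.items():
        out[f"V({name})/total"] = r
    return pd.Series(out)


def bootstrap_varcomp(table: pd.DataFrame, loci: Sequence[LocusSpec],
                      trait: str, B: int = 1000, seed: int = 0,
                      covariates: Sequence[str] = (), components="full",
                      phased: bool = False, weights: str = "observed",
                      level: float = 0.95) -> BootstrapResult:
    """Bootstrap the genetic variance/covariance components.

    Subjects (rows of ``table``) are resampled with replacement ``B`` times.
    Allele frequencies are re-estimated inside every replicate.  Replicates
    in which some allele is entirely absent (monomorphic locus: the full
    design is singular and the components are not identifiable) are skipped
    and counted in ``n_skipped``.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    point = _varcomp_quantities(table, loci, trait, covariates, components,
                                phased, weights)
    if point is None:
        raise ValueError("a locus is monomorphic in the observed sample")
    n = len(table)
    reps = []
    n_skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        rep = _varcomp_quantities(table.iloc[idx].reset_index(drop=True),
                                  loci, trait, covariates, components,
                                  phased, weights)
        if rep is None:
            n_skipped += 1
        else:
            reps.append(rep)
    if not reps:
        raise ValueError("all bootstrap replicates were skipped")
    replicates = pd.DataFrame(reps).reset_index(drop=True)
    alpha = 1.0 - level
    ci = pd.DataFrame({
        "lower": replicates.quantile(alpha / 2),
        "upper": replicates.quantile(1 - alpha / 2),
    })
    se = replicates.std(ddof=1) if len(replicates) >= 2 else None
    return BootstrapResult(point=point, replicates=replicates, ci=ci, se=se,
                           B=B, n_skipped=n_skipped, seed=seed, level=level)


def component_existence_test(table: pd.DataFrame, loci: Sequence[LocusSpec],
                             component, trait: str, B: int = 200,
                             seed: int = 0, covariates: Sequence[str] = (),
                             phased: bool = False) -> dict:
    """Null-imposed bootstrap test for the existence of one variance
    component.

    Variance components live on the boundary of the parameter space (they
    are nonnegative), so a percentile CI of case-resampled estimates cannot
    calibrate a test of ``V = 0``: every resampled estimate is positive.
    This test instead imposes the null: the model *without* the component is
    fitted, bootstrap responses are built as its fitted values plus
    resampled residuals, the full model is refitted to each, and the
    observed component variance is compared with this null distribution.
    The p-value is ``(1 + #{V* >= V_obs}) / (B + 1)``.

    The genotypes (and hence the design and allele frequencies) are held
    fixed across replicates; only the trait is resampled, matching the
    regression view of the coding variables as fixed covariates.
    """
    model = GMAModel.from_subject_table(table, loci, trait,
                                        covariates=covariates,
                                        components="full", phased=phased,
                                        estimate_freqs=True)
    design = model.design
    key = (component if isinstance(component, ComponentKey)
           else ComponentKey.from_name(component, design.loci, phased))
    name = key.name(design.loci)
    cols = design.columns_of(key)
    if cols.size == 0:
        raise ValueError(f"component {name} not in the design")
    rng = np.random.default_rng(seed)
    w = model.weights
    sw = np.sqrt(w)
    X_full = np.column_stack([design.X, model.exog_covariates])
    keep = [c for c in range(X_full.shape[1]) if c not in set(cols)]
    X_red = X_full[:, keep]
    Xw_full = X_full * sw[:, None]
    Xw_red = X_red * sw[:, None]
    P_full = np.linalg.pinv(Xw_full)
    y = model.endog

    def v_component(beta_full: np.ndarray) -> float:
        score = X_full[:, cols] @ beta_full[cols]
        W = w / w.sum()
        mean = W @ score
        return float(W @ (score - mean) ** 2)

    beta_obs = P_full @ (y * sw)
    v_obs = v_component(beta_obs)
    beta_red, *_ = np.linalg.lstsq(Xw_red, y * sw, rcond=None)
    fitted_red = X_red @ beta_red
    resid_red = y - fitted_red
    n = len(y)
    exceed = 0
    null_draws = np.empty(B)
    for b in range(B):
        y_star = fitted_red + resid_red[rng.integers(0, n, n)]
        beta_star = P_full @ (y_star * sw)
        null_draws[b] = v_component(beta_star)
        if null_draws[b] >= v_obs:
            exceed += 1
    return {
        "component": name,
        "statistic": v_obs,
        "pvalue": (1 + exceed) / (B + 1),
        "B": B,
        "null_quantiles": {
            "50%": float(np.quantile(null_draws, 0.5)),
            "95%": float(np.quantile(null_draws, 0.95)),
        },
    }


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStep:
    component: ComponentKey
    name: str
    lr: float
    pvalue: float
    df: int
    model_size: int     # columns incl. intercept after the step
    rss: float


@dataclass
class SelectionTrace:
    """Record of a hierarchical forward selection run."""

    steps: list[SelectionStep] = field(default_factory=list)
    selected: list[ComponentKey] = field(default_factory=list)
    alpha: float = 0.05
    final_rss: float = float("nan")

    @property
    def selected_names(self) -> list[str]:
        return [s.name for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "final_rss": self.final_rss,
            "steps": [
                {"component": s.name, "LR": s.lr, "pvalue": s.pvalue,
                 "df": s.df, "model_size": s.model_size, "rss": s.rss}
                for s in self.steps
            ],
        }


def _wrss(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, int]:
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    return float(r @ r), int(np.linalg.matrix_rank(Xw))


def forward_select(table: pd.DataFrame, loci: Sequence[LocusSpec], trait: str,
                   alpha: float = 0.05, candidates=None,
                   covariates: Sequence[str] = (), phased: bool = False,
                   allow_drop: bool = False) -> SelectionTrace:
    """Hierarchical forward selection of genetic components.

    At each step the not-yet-included components are scanned by ascending
    order (single alleles before pairs before higher epistasis); within the
    lowest order containing a qualifying candidate, the component with the
    largest likelihood-ratio improvement enters if its chi-square p-value is
    below ``alpha``.  Selection stops when no candidate qualifies at any
    order.  The LR statistic uses the Gaussian working likelihood
    ``n * log(RSS0 / RSS1)`` with degrees of freedom equal to the rank added
    by the component's columns.

    With ``allow_drop=True`` a backward pass runs after selection,
    re-testing each selected component given the others and dropping the
    least significant while its p-value exceeds ``alpha``."""
    model = GMAModel.from_subject_table(table, loci, trait,
                                        covariates=covariates,
                                        components="full", phased=phased,
                                        estimate_freqs=True)
    design = model.design
    y = model.endog
    w = model.weights
    n = design.n_rows
    if candidates is None:
        cand = list(design.components)
    else:
        cand = [(c if isinstance(c, ComponentKey)
                 else ComponentKey.from_name(c, design.loci, phased))
                for c in candidates]
    cand = sorted(set(cand), key=ComponentKey.sort_key)
    cov = model.exog_covariates

    def matrix(keys: Sequence[ComponentKey]) -> np.ndarray:
        cols = [0] + [c for k in keys for c in design.columns_of(k)]
        return np.column_stack([design.X[:, cols], cov])

    selected: list[ComponentKey] = []
    trace = SelectionTrace(alpha=alpha)
    rss0, rank0 = _wrss(matrix(selected), y, w)
    while True:
        remaining = [k for k in cand if k not in selected]
        best = None
        for order in sorted({k.order for k in remaining}):
            tier = [k for k in remaining if k.order == order]
            for key in tier:
                rss1, rank1 = _wrss(matrix(selected + [key]), y, w)
                df = rank1 - rank0
                if df <= 0:
                    logger.warning("component %s adds no rank; skipped",
                                   key.name(design.loci))
                    continue
                if rss1 <= 0:
                    lr, p = float("inf"), 0.0
                else:
                    lr = n * np.log(rss0 / rss1)
                    p = float(stats.chi2.sf(lr, df))
                if p < alpha and (best is None or lr > best[1]):
                    best = (key, lr, p, df, rss1, rank1)
            if best is not None:
                break
        if best is None:
            break
        key, lr, p, df, rss1, rank1 = best
        selected.append(key)
        rss0, rank0 = rss1, rank1
        trace.steps.append(SelectionStep(
            component=key, name=key.name(design.loci), lr=float(lr),
            pvalue=p, df=df, model_size=matrix(selected).shape[1], rss=rss1))

    if allow_drop:
        changed = True
        while changed and selected:
            changed = False
            worst = None
            for key in selected:
                others = [k for k in selected if k != key]
                rss_red, _ = _wrss(matrix(others), y, w)
                rss_full, rank_full = _wrss(matrix(selected), y, w)
                df = rank_full - _wrss(matrix(others), y, w)[1]
                lr = n * np.log(rss_red / rss_full) if rss_full > 0 else float("inf")
                p = float(stats.chi2.sf(lr, max(df, 1)))
                if p >= alpha and (worst is None or p > worst[1]):
                    worst = (key, p)
            if worst is not None:
                selected.remove(worst[0])
                changed = True
        rss0, rank0 = _wrss(matrix(selected), y, w)

    trace.selected = selected
    trace.final_rss = rss0
    return trace
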