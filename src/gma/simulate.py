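"""Synthetic genotype/phenotype generation for parameter-recovery testing.

A :class:`PopulationModel` bundles the loci (with their gamete allele
frequencies), an optional explicit gamete distribution per parent (to induce
linkage disequilibrium), an optional explicit joint genotype-class
distribution (to induce Hardy-Weinberg disequilibrium exactly — e.g. a
published genotype-frequency table), and the generative trait model: an
intercept, GMA coefficients keyed by design column name, and a Gaussian
residual standard deviation.

Under the defaults — independent paternal and maternal gamete draws from
identical linkage-equilibrium gamete tables — the population is in
Hardy-Weinberg, linkage and gametic equilibrium, which is the setting in
which the GMA variance partition is orthogonal; the generator exists
precisely so that estimators can be checked against known truth in and out
of that setting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import ClassTable, Genotype, LocusSpec, estimate_allele_freqs
from .design import build_design

__all__ = ["PopulationModel", "simulate_genotypes", "simulate_phenotypes"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PopulationModel:
    """Generative population + trait model.

    Parameters
    ----------
    loci : sequence of LocusSpec
        Must carry allele frequencies (the generative truth).
    mu : float
        Intercept (population mean genotypic value in equilibrium).
    coeffs : mapping column-name -> float
        GMA coefficients of the full design (missing names are zero); the
        names are those of ``build_design(..., "full", phased).column_names``.
    sigma : float
        Residual standard deviation of the Gaussian environmental noise.
    phased : bool
        Whether genotype tokens carry phase (``A|B``) or not (``A/B``).
    gametes_paternal, gametes_maternal : (haplotypes, probs), optional
        Explicit gamete distributions over tuples of per-locus alleles;
        supplying a non-product distribution induces linkage
        disequilibrium.  Defaults to the product of the per-locus allele
        frequencies (linkage equilibrium).
    class_freqs : (genotype DataFrame, probs), optional
        Explicit joint genotype-class distribution; sampling classes
        directly induces arbitrary Hardy-Weinberg disequilibrium (and
        reproduces a published genotype-frequency table exactly, up to
        multinomial noise).
    """

    loci: tuple[LocusSpec, ...]
    mu: float = 0.0
    coeffs: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 1.0
    phased: bool = False
    gametes_paternal: tuple[list[tuple], np.ndarray] | None = None
    gametes_maternal: tuple[list[tuple], np.ndarray] | None = None
    class_freqs: tuple[pd.DataFrame, np.ndarray] | None = None

    def __post_init__(self):
        self.loci = tuple(self.loci)
        if "mu" in self.coeffs:
            raise ValueError("pass the intercept via 'mu', not in coeffs")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        valid = set(self.design_columns())
        unknown = set(self.coeffs) - valid
        if unknown:
            raise ValueError(f"coefficient labels not in the full design: "
                             f"{sorted(unknown)}")
        for gt, side in ((self.gametes_paternal, "paternal"),
                         (self.gametes_maternal, "maternal")):
            if gt is None:
                continue
            haps, probs = gt
            probs = np.asarray(probs, dtype=float)
            if len(haps) != len(probs) or (probs < 0).any():
                raise ValueError(f"invalid {side} gamete table")
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"{side} gamete probabilities must sum to 1")
            # marginals must agree with the per-locus frequencies
            for k, loc in enumerate(self.loci):
                want = loc.p_pat if side == "paternal" else loc.p_mat
                marg = np.zeros(loc.m)
                for h, pr in zip(haps, probs):
                    marg[loc.index(h[k])] += pr
                if not np.allclose(marg, want, atol=1e-6):
                    raise ValueError(
                        f"{side} gamete marginals at {loc.locus_id} do not "
                        f"match its allele frequencies")
        if self.class_freqs is not None:
            gdf, probs = self.class_freqs
            probs = np.asarray(probs, dtype=float)
            if len(gdf) != len(probs) or (probs < 0).any():
                raise ValueError("invalid genotype-class table")
            self.class_freqs = (gdf.reset_index(drop=True), probs)

    # ------------------------------------------------------------------
    def design_columns(self) -> list[str]:
        """Column names of the full design this model's coefficients use."""
        from .design import joint_classes
        proto = joint_classes(self.loci, self.phased)
        return build_design(proto, self.loci, "full",
                            phased=self.phased).column_names

    def coefficient_series(self) -> pd.Series:
        """Full coefficient vector (zeros filled in), intercept included."""
        names = self.design_columns()
        vals = [self.mu] + [float(self.coeffs.get(nm, 0.0))
                            for nm in names[1:]]
        return pd.Series(vals, index=names)

    @classmethod
    def from_class_table(cls, table: ClassTable, loci: Sequence[LocusSpec],
                         trait: str, sigma: float = 0.0,
                         sample_classes: bool = True) -> "PopulationModel":
        """Generative model whose genotypic values are a class table's trait
        means: the saturated GMA fit to the table supplies the coefficients,
        and (optionally) the table's class frequencies drive genotype
        sampling, reproducing its Hardy-Weinberg disequilibrium."""
        from .model import GMAModel
        loci = list(loci)
        for k, loc in enumerate(loci):
            if not loc.has_freqs:
                p = estimate_allele_freqs(table.genotypes[loc.locus_id], loc,
                                          weights=table.frequency)
                loci[k] = loc.with_freqs(pooled=p)
        res = GMAModel.from_class_table(table, loci, trait).fit()
        coeffs = {nm: float(v) for nm, v in res.params.items() if nm != "mu"}
        cf = ((table.genotypes.copy(), np.asarray(table.frequency, float) /
               float(np.sum(table.frequency))) if sample_classes else None)
        return cls(loci=tuple(loci), mu=res.mu, coeffs=coeffs, sigma=sigma,
                   phased=False, class_freqs=cf)

    # ------------------------------------------------------------------
    def _gamete_table(self, side: str):
        explicit = (self.gametes_paternal if side == "paternal"
                    else self.gametes_maternal)
        if explicit is not None:
            return explicit
        haps = list(itertools.product(*[l.alleles for l in self.loci]))
        probs = np.ones(len(haps))
        for k, loc in enumerate(self.loci):
            p = loc.p_pat if side == "paternal" else loc.p_mat
            for h_idx, h in enumerate(haps):
                probs[h_idx] *= p[loc.index(h[k])]
        return haps, probs / probs.sum()

    def simulate_genotypes(self, n: int, seed=0) -> pd.DataFrame:
        """Draw ``n`` subjects' joint genotypes.

        With ``class_freqs`` set, classes are drawn directly from that
        distribution.  Otherwise one paternal and one maternal gamete are
        drawn independently (gametic equilibrium + HWE), each from its
        parent's gamete table."""
        rng = _as_rng(seed)
        ids = [l.locus_id for l in self.loci]
        if self.class_freqs is not None:
            gdf, probs = self.class_freqs
            idx = rng.choice(len(gdf), size=n, p=probs / probs.sum())
            return gdf.iloc[idx].reset_index(drop=True)
        hapsP, pP = self._gamete_table("paternal")
        hapsM, pM = self._gamete_table("maternal")
        iP = rng.choice(len(hapsP), size=n, p=pP)
        iM = rng.choice(len(hapsM), size=n, p=pM)
        cols = {}
        for k, lid in enumerate(ids):
            toks = []
            for a, b in zip(iP, iM):
                g = Genotype(hapsP[a][k], hapsM[b][k], phased=self.phased)
                toks.append(g.token())
            cols[lid] = toks
        return pd.DataFrame(cols)

    def genotypic_values(self, genotypes: pd.DataFrame) -> np.ndarray:
        """Deterministic E(G|g) per row under the generative coefficients."""
        design = build_design(genotypes, self.loci, "full", phased=self.phased)
        beta = self.coefficient_series()
        return design.X @ beta.to_numpy()

    def simulate_phenotypes(self, genotypes: pd.DataFrame,
                            seed=0) -> np.ndarray:
        """Phenotypes ``y = E(G|g) + N(0, sigma^2)`` noise; with
        ``sigma = 0`` the deterministic genotypic values are returned."""
        rng = _as_rng(seed)
        g = self.genotypic_values(genotypes)
        if self.sigma == 0:
            return g
        return g + rng.normal(0.0, self.sigma, size=len(g))

    def simulate(self, n: int, seed=0, trait: str = "y") -> pd.DataFrame:
        """Genotypes plus a phenotype column, seed-deterministic."""
        rng = _as_rng(seed)
        gdf = self.simulate_genotypes(n, rng)
        gdf[trait] = self.simulate_phenotypes(gdf, rng)
        return gdf


def simulate_genotypes(model: PopulationModel, n: int, seed=0,
                       phase_known: bool | None = None) -> pd.DataFrame:
    """Functional wrapper over :meth:`PopulationModel.simulate_genotypes`."""
    if phase_known is not None and phase_known != model.phased:
        model = PopulationModel(model.loci, model.mu, dict(model.coeffs),
                                model.sigma, phase_known,
                                model.gametes_paternal, model.gametes_maternal,
                                model.class_freqs)
    return model.simulate_genotypes(n, seed)


def simulate_phenotypes(model: PopulationModel, genotypes: pd.DataFrame,
                        seed=0) -> np.ndarray:
    """Functional wrapper over :meth:`PopulationModel.simulate_phenotypes`."""
    return model.simulate_phenotypes(genotypes, seed)
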