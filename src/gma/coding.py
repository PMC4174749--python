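"""Allele bookkeeping and genotype coding for general multi-allele (GMA) models.

The basic building blocks of every GMA design column live here:

* :class:`LocusSpec` — the allele catalog of a locus, its paternal/maternal
  (or pooled) allele frequencies and the baseline allele whose effect is
  absorbed into the remaining parameters.
* :class:`Genotype` — one subject's allele pair at a locus, phased
  (``"A|B"``, paternal first) or unphased (``"A/B"``, canonically sorted).
* :func:`estimate_allele_freqs` — gene-counting frequency estimation.
* :func:`index_variables_phased` — the mean-corrected index variables
  ``x_P``/``x_M`` (indicator of allele transmission minus its frequency).
* :func:`coding_variables_unphased` — the combined genotype coding variables
  ``w_i = x_Pi + x_Mi`` and ``v_ij = x_Pi x_Mj + x_Pj x_Mi`` that remain well
  defined when parental origin is unknown.

Every coding variable has mean zero in a population whose allele frequencies
match the ones used to build it; this is what makes the genetic components
orthogonal in equilibrium populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {".", "", "./.", ".|."}

__all__ = [
    "LocusSpec",
    "Genotype",
    "ClassTable",
    "CatalogError",
    "PhaseError",
    "EstimationError",
    "estimate_allele_freqs",
    "index_variables_phased",
    "coding_variables_unphased",
]


class CatalogError(KeyError):
    """An allele label not present in the locus catalog was encountered."""


class PhaseError(ValueError):
    """A phase-known computation was requested on unphased genotypes."""


class EstimationError(ValueError):
    """Allele frequencies cannot be estimated (e.g. all genotypes missing)."""


@dataclass(frozen=True)
class Genotype:
    """A single-locus genotype: an allele pair, phased or unphased.

    For phased genotypes ``a1`` is the paternal and ``a2`` the maternal
    allele.  Unphased pairs are stored in canonical (sorted) order, so
    ``A/B`` and ``B/A`` compare equal.  A missing genotype has both alleles
    ``None``.
    """

    a1: str | None
    a2: str | None
    phased: bool = False

    def __post_init__(self):
        if (self.a1 is None) != (self.a2 is None):
            raise ValueError("both alleles must be present or both missing")
        if not self.phased and self.a1 is not None and self.a1 > self.a2:
            a1, a2 = self.a2, self.a1
            object.__setattr__(self, "a1", a1)
            object.__setattr__(self, "a2", a2)

    @property
    def missing(self) -> bool:
        return self.a1 is None

    @classmethod
    def from_token(cls, token: str) -> "Genotype":
        """Parse ``"A|B"`` (phased, paternal first), ``"A/B"`` (unphased) or
        ``"."`` (missing)."""
        token = token.strip() if isinstance(token, str) else token
        if token is None or (isinstance(token, float) and np.isnan(token)):
            return cls(None, None)
        if token in MISSING_TOKENS:
            return cls(None, None)
        if "|" in token:
            a1, a2 = token.split("|")
            return cls(a1, a2, phased=True)
        if "/" in token:
            a1, a2 = token.split("/")
            return cls(a1, a2, phased=False)
        raise ValueError(f"malformed genotype token {token!r}")

    def token(self) -> str:
        if self.missing:
            return "."
        sep = "|" if self.phased else "/"
        return f"{self.a1}{sep}{self.a2}"

    def unphase(self) -> "Genotype":
        return Genotype(self.a1, self.a2, phased=False)

    def count(self, allele: str) -> int:
        return int(self.a1 == allele) + int(self.a2 == allele)


def _as_freq_tuple(freqs: Mapping[str, float], alleles: Sequence[str],
                   what: str) -> tuple[float, ...]:
    unknown = set(freqs) - set(alleles)
    if unknown:
        raise CatalogError(f"{what}: alleles {sorted(unknown)} not in catalog")
    vals = tuple(float(freqs.get(a, 0.0)) for a in alleles)
    if any(v < 0 for v in vals):
        raise ValueError(f"{what}: negative allele frequency")
    total = sum(vals)
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"{what}: frequencies sum to {total:.4f}, not 1")
    if abs(total - 1.0) > 1e-9:
        # Accepted as-is (e.g. published tables rounded to 4 decimals);
        # renormalizing would change every downstream coding value.
        logger.warning("%s: frequencies sum to %.6f; kept as given", what, total)
    return vals


@dataclass(frozen=True)
class LocusSpec:
    """Allele catalog, allele frequencies and baseline allele of one locus.

    Parameters
    ----------
    locus_id : str
        Identifier; also the genotype column name in subject tables.
    alleles : sequence of str
        Ordered allele catalog (length ``m >= 2``).
    freq_paternal, freq_maternal : mapping allele -> frequency
        Gamete allele frequencies.  Pass the same mapping (or use
        :meth:`with_pooled_freqs`) for pooled, phase-unknown use.
    baseline : str, optional
        The allele absorbed into the remaining parameters; defaults to the
        last allele of the catalog.
    """

    locus_id: str
    alleles: tuple[str, ...]
    freq_paternal: tuple[float, ...] | None = None
    freq_maternal: tuple[float, ...] | None = None
    baseline: str = ""

    def __init__(self, locus_id, alleles,
                 freq_paternal: Mapping[str, float] | Sequence[float] | None = None,
                 freq_maternal: Mapping[str, float] | Sequence[float] | None = None,
                 baseline: str | None = None):
        alleles = tuple(str(a) for a in alleles)
        if len(alleles) < 2:
            raise ValueError("a locus needs at least two alleles")
        if len(set(alleles)) != len(alleles):
            raise ValueError("duplicate allele labels")
        if baseline is None:
            baseline = alleles[-1]
        if baseline not in alleles:
            raise CatalogError(f"baseline {baseline!r} not in catalog {alleles}")

        def norm(f, what):
            if f is None:
                return None
            if not isinstance(f, Mapping):
                f = dict(zip(alleles, f))
            return _as_freq_tuple(f, alleles, f"{locus_id} ({what})")

        object.__setattr__(self, "locus_id", str(locus_id))
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "freq_paternal", norm(freq_paternal, "paternal"))
        object.__setattr__(self, "freq_maternal", norm(freq_maternal, "maternal"))
        object.__setattr__(self, "baseline", baseline)

    # -- frequency access -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.alleles)

    @property
    def has_freqs(self) -> bool:
        return self.freq_paternal is not None and self.freq_maternal is not None

    @property
    def pooled(self) -> bool:
        """True when paternal and maternal frequencies coincide."""
        return (self.has_freqs
                and np.allclose(self.freq_paternal, self.freq_maternal, atol=0.0))

    @property
    def p_pat(self) -> np.ndarray:
        if self.freq_paternal is None:
            raise ValueError(f"{self.locus_id}: no paternal frequencies set")
        return np.asarray(self.freq_paternal)

    @property
    def p_mat(self) -> np.ndarray:
        if self.freq_maternal is None:
            raise ValueError(f"{self.locus_id}: no maternal frequencies set")
        return np.asarray(self.freq_maternal)

    @property
    def p(self) -> np.ndarray:
        """Pooled allele frequencies (requires paternal == maternal)."""
        if not self.pooled:
            raise PhaseError(
                f"{self.locus_id}: pooled frequencies requested but paternal "
                "and maternal frequencies differ or are unset")
        return self.p_pat

    def freq(self, allele: str) -> float:
        return self.p[self.index(allele)]

    # -- catalog helpers ---------------------------------------------------
    def index(self, allele: str) -> int:
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise CatalogError(f"allele {allele!r} not in catalog of "
                               f"{self.locus_id}") from None

    @property
    def nonbaseline(self) -> tuple[str, ...]:
        """Catalog order with the baseline allele removed (the indices
        ``1..m-1`` of the model parameters)."""
        return tuple(a for a in self.alleles if a != self.baseline)

    def with_freqs(self, pooled=None, paternal=None, maternal=None) -> "LocusSpec":
        if pooled is not None:
            paternal = maternal = pooled
        return LocusSpec(self.locus_id, self.alleles, paternal, maternal,
                         self.baseline)

    def with_baseline(self, baseline: str) -> "LocusSpec":
        return LocusSpec(self.locus_id, self.alleles, self.freq_paternal,
                         self.freq_maternal, baseline)

    def genotype(self, token: str) -> Genotype:
        g = Genotype.from_token(token)
        if not g.missing:
            self.index(g.a1), self.index(g.a2)
        return g

    def unphased_classes(self) -> list[Genotype]:
        """All ``m(m+1)/2`` unphased genotype classes, homozygote-diagonal
        last index varying fastest (AA, AB, BB, AC, BC, CC ... pattern)."""
        out = []
        for j, aj in enumerate(self.alleles):
            for i in range(j + 1):
                out.append(Genotype(self.alleles[i], aj, phased=False))
        return out

    def phased_classes(self) -> list[Genotype]:
        """All ``m**2`` phased classes, paternal allele varying slowest."""
        return [Genotype(ai, aj, phased=True)
                for ai in self.alleles for aj in self.alleles]


@dataclass
class ClassTable:
    """A genotype-class summary table: one row per distinct joint genotype,
    with its population frequency (or count) and, optionally, the expected
    genotypic value for one or more traits."""

    genotypes: pd.DataFrame          # one column per locus, genotype tokens
    frequency: np.ndarray
    traits: pd.DataFrame | None = None

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        if (self.frequency < 0).any():
            raise ValueError("negative class frequency")
        if len(self.frequency) != len(self.genotypes):
            raise ValueError("frequency length mismatch")
        # canonicalize tokens so AiAj == AjAi, then enforce uniqueness
        canon = self.genotypes.apply(
            lambda col: col.map(lambda t: Genotype.from_token(t).token()))
        if canon.duplicated().any():
            dup = canon[canon.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate genotype class {dup}")
        self.genotypes = canon.reset_index(drop=True)
        if self.traits is not None:
            self.traits = self.traits.reset_index(drop=True)

    @property
    def n_classes(self) -> int:
        return len(self.genotypes)

    @property
    def trait_names(self) -> list[str]:
        return [] if self.traits is None else list(self.traits.columns)

    def trait(self, name: str) -> np.ndarray:
        if self.traits is None or name not in self.traits:
            raise KeyError(f"unknown trait {name!r}")
        return self.traits[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# allele frequency estimation (gene counting)
# ---------------------------------------------------------------------------

def _genotype_list(genotypes: Iterable) -> list[Genotype]:
    out = []
    for g in genotypes:
        out.append(g if isinstance(g, Genotype) else Genotype.from_token(g))
    return out


def estimate_allele_freqs(genotypes: Iterable, locus: LocusSpec,
                          mode: str = "pooled",
                          weights: Sequence[float] | None = None):
    """Gene-counting allele frequency estimation at one locus.

    In ``"pooled"`` mode each subject contributes both alleles: the frequency
    of allele ``A`` is its homozygote share plus half of every heterozygote
    share containing it.  In ``"by-parent"`` mode paternal and maternal
    alleles are counted separately, which requires phased genotypes.

    Parameters
    ----------
    genotypes : iterable of Genotype or genotype tokens
        Missing genotypes are excluded.
    locus : LocusSpec
        Supplies the allele catalog (frequencies on it are ignored).
    weights : sequence of float, optional
        Per-row class probabilities (e.g. published genotype frequencies).
        When given they are used as-is — frequencies derived from rounded
        published tables are deliberately *not* renormalized, so their sum
        reproduces the table's round-off.  Without weights each subject
        counts equally and frequencies sum to 1 exactly.

    Returns
    -------
    dict allele -> frequency, or a ``(paternal, maternal)`` pair of dicts in
    ``"by-parent"`` mode.
    """
    gs = _genotype_list(genotypes)
    if weights is None:
        wts = None
    else:
        wts = np.asarray(weights, dtype=float)
        if len(wts) != len(gs):
            raise ValueError("weights length mismatch")
    keep = [k for k, g in enumerate(gs) if not g.missing]
    if not keep:
        raise EstimationError(f"{locus.locus_id}: all genotypes missing")
    for k in keep:  # catalog check
        locus.index(gs[k].a1), locus.index(gs[k].a2)

    if mode == "pooled":
        acc = dict.fromkeys(locus.alleles, 0.0)
        for k in keep:
            w = 1.0 if wts is None else wts[k]
            acc[gs[k].a1] += 0.5 * w
            acc[gs[k].a2] += 0.5 * w
        if wts is None:
            n = len(keep)
            return {a: c / n for a, c in acc.items()}
        return acc
    if mode == "by-parent":
        if any(not gs[k].phased for k in keep):
            raise PhaseError("by-parent estimation requires phased genotypes")
        pat = dict.fromkeys(locus.alleles, 0.0)
        mat = dict.fromkeys(locus.alleles, 0.0)
        for k in keep:
            w = 1.0 if wts is None else wts[k]
            pat[gs[k].a1] += w
            mat[gs[k].a2] += w
        if wts is None:
            n = len(keep)
            pat = {a: c / n for a, c in pat.items()}
            mat = {a: c / n for a, c in mat.items()}
        return pat, mat
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# index and coding variables
# ---------------------------------------------------------------------------

def index_variables_phased(g: Genotype | str, locus: LocusSpec):
    """Mean-corrected index variables of a phased genotype.

    Returns ``(x_P, x_M)``, each of length ``m``:
    ``x_Pi = 1 - p^i`` if the paternal allele is ``A_i``, else ``-p^i``
    (and analogously for the maternal side).  Each vector sums to zero
    exactly, because exactly one transmission indicator is 1.
    """
    if isinstance(g, str):
        g = Genotype.from_token(g)
    if g.missing:
        raise ValueError("missing genotype")
    if not g.phased:
        raise PhaseError("phase-known coding requested on unphased genotype")
    x_p = -locus.p_pat.copy()
    x_m = -locus.p_mat.copy()
    x_p[locus.index(g.a1)] += 1.0
    x_m[locus.index(g.a2)] += 1.0
    return x_p, x_m


def coding_variables_unphased(g: Genotype | str, locus: LocusSpec):
    """Combined genotype coding variables of an unphased genotype.

    Returns ``(w, V)`` where ``w`` has length ``m - 1`` (one entry per
    non-baseline allele, ``w_i = x_Pi + x_Mi``) and ``V`` is the symmetric
    ``(m-1) x (m-1)`` matrix with ``V[i, i] = x_Pi * x_Mi`` and
    ``V[i, j] = x_Pi x_Mj + x_Pj x_Mi`` for ``i != j``.  Both are invariant
    under swapping the two alleles, hence well defined without phase.
    """
    if isinstance(g, str):
        g = Genotype.from_token(g)
    if g.missing:
        raise ValueError("missing genotype")
    if not locus.pooled:
        raise PhaseError(f"{locus.locus_id}: unphased coding requires pooled "
                         "allele frequencies")
    p = locus.p
    # any phase assignment gives the same w and V: build x for (a1|a2)
    x_p = -p.copy()
    x_m = -p.copy()
    x_p[locus.index(g.a1)] += 1.0
    x_m[locus.index(g.a2)] += 1.0
    sel = [locus.index(a) for a in locus.nonbaseline]
    xp, xm = x_p[sel], x_m[sel]
    w = xp + xm
    V = np.outer(xp, xm)
    V = V + V.T - np.diag(np.diag(V))
    return w, V
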