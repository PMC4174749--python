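"""GMA design matrices and the genetic-component bookkeeping behind them.

A GMA design column is a product, over the modeled loci, of mean-corrected
coding variables (``x_P``/``x_M`` when phase is known, ``w``/``v`` when it is
not).  Columns that involve the same loci with the same per-locus allele
counts (and, for phased models, the same parental origins) form one *genetic
component*; variance components are variances of these per-component sums.

* :class:`ComponentKey` identifies a component: per locus either the pair of
  paternal/maternal involvement indicators (phased) or the number of alleles
  involved, 0/1/2 (unphased).
* :class:`EffectLabel` identifies a single coefficient within a component by
  its allele indices (non-baseline alleles only).
* :func:`build_design` assembles the numeric matrix for a full or reduced
  model; :func:`f_infinity_design` builds the analogous matrix from raw
  inheritance indicators (the F-infinity parameterization), whose columns are
  *not* mean-corrected and therefore confounded across orders even in
  equilibrium populations.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import ClassTable, Genotype, LocusSpec, PhaseError

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentKey",
    "EffectLabel",
    "DesignMatrix",
    "build_design",
    "f_infinity_design",
    "enumerate_components",
    "joint_classes",
]


@dataclass(frozen=True)
class ComponentKey:
    """Identity of one genetic component.

    ``key`` holds one entry per locus: for unphased models an integer in
    {0, 1, 2} (how many alleles at that locus are involved), for phased
    models a pair ``(i, j)`` of 0/1 indicators for the presence of a
    paternal / maternal allele.  The all-zero key is the intercept.
    """

    phased: bool
    key: tuple

    def __post_init__(self):
        if self.phased:
            ok = all(tuple(e) in {(0, 0), (0, 1), (1, 0), (1, 1)}
                     for e in self.key)
        else:
            ok = all(e in (0, 1, 2) for e in self.key)
        if not ok:
            raise ValueError(f"invalid component key {self.key}")
        object.__setattr__(self, "key", tuple(
            tuple(e) if self.phased else int(e) for e in self.key))

    @property
    def order(self) -> int:
        """Total number of alleles involved (``na`` of the model term)."""
        if self.phased:
            return sum(i + j for i, j in self.key)
        return sum(self.key)

    @property
    def is_intercept(self) -> bool:
        return self.order == 0

    def name(self, loci: Sequence[LocusSpec] | Sequence[str]) -> str:
        ids = [l.locus_id if isinstance(l, LocusSpec) else str(l) for l in loci]
        parts = []
        for lid, e in zip(ids, self.key):
            if self.phased:
                tag = {(1, 0): "A_P", (0, 1): "A_M", (1, 1): "D"}.get(tuple(e))
            else:
                tag = {1: "A", 2: "D"}.get(e)
            if tag:
                parts.append(f"{tag}({lid})")
        return "x".join(parts) if parts else "mu"

    @classmethod
    def intercept(cls, n_loci: int, phased: bool) -> "ComponentKey":
        zero = (0, 0) if phased else 0
        return cls(phased, tuple([zero] * n_loci))

    @classmethod
    def from_name(cls, name: str,
                  loci: Sequence[LocusSpec] | Sequence[str],
                  phased: bool) -> "ComponentKey":
        """Parse names such as ``"A(1)"``, ``"D(acp1)"``, ``"A(1)xA(2)"`` or
        ``"A_P(1)xD(2)"`` against the given locus list."""
        ids = [l.locus_id if isinstance(l, LocusSpec) else str(l) for l in loci]
        key = [(0, 0) if phased else 0 for _ in ids]
        if name.strip() in ("mu", "1", "intercept"):
            return cls(phased, tuple(key))
        for part in name.split("x"):
            m = re.fullmatch(r"\s*(A_P|A_M|A|D)\(([^)]+)\)\s*", part)
            if not m:
                raise ValueError(f"cannot parse component factor {part!r}")
            tag, lid = m.group(1), m.group(2)
            if lid not in ids:
                raise ValueError(f"unknown locus {lid!r} in {name!r}")
            k = ids.index(lid)
            if phased:
                add = {"A_P": (1, 0), "A_M": (0, 1), "D": (1, 1)}.get(tag)
                if add is None:
                    raise ValueError(f"{tag} is not a phased component factor")
                cur = key[k]
                new = (cur[0] + add[0], cur[1] + add[1])
                if new[0] > 1 or new[1] > 1:
                    raise ValueError(f"locus {lid} repeated in {name!r}")
                key[k] = new
            else:
                add = {"A": 1, "D": 2}.get(tag)
                if add is None:
                    raise ValueError(f"{tag} is not an unphased component "
                                     "factor (no parental origin available)")
                if key[k] != 0:
                    raise ValueError(f"locus {lid} repeated in {name!r}")
                key[k] = add
        return cls(phased, tuple(key))

    def sort_key(self):
        if self.phased:
            flat = tuple(x for e in self.key for x in e)
        else:
            flat = self.key
        return (self.order, tuple(-x for x in flat))


@dataclass(frozen=True)
class EffectLabel:
    """One coefficient of a GMA model: a component plus the specific
    (non-baseline) allele labels involved at each locus.

    ``alleles`` has one tuple per locus: ``()`` when the locus is not
    involved; unphased ``(s,)`` or ``(s, t)`` with ``s <= t``; phased
    ``(s, None)`` paternal-only, ``(None, t)`` maternal-only, ``(s, t)``
    both.
    """

    component: ComponentKey
    alleles: tuple

    @property
    def is_intercept(self) -> bool:
        return self.component.is_intercept

    def name(self, loci: Sequence[LocusSpec] | Sequence[str]) -> str:
        if self.is_intercept:
            return "mu"
        ids = [l.locus_id if isinstance(l, LocusSpec) else str(l) for l in loci]
        parts = []
        for lid, e, al in zip(ids, self.component.key, self.alleles):
            if self.component.phased:
                i, j = e
                if (i, j) == (0, 0):
                    continue
                if (i, j) == (1, 0):
                    parts.append(f"aP({lid}={al[0]})")
                elif (i, j) == (0, 1):
                    parts.append(f"aM({lid}={al[1]})")
                else:
                    parts.append(f"d({lid}={al[0]}|{al[1]})")
            else:
                if e == 0:
                    continue
                if e == 1:
                    parts.append(f"a({lid}={al[0]})")
                else:
                    parts.append(f"d({lid}={al[0]},{al[1]})")
        return "*".join(parts)


def enumerate_components(loci: Sequence[LocusSpec], phased: bool
                         ) -> list[ComponentKey]:
    """All genetic components of the full model, by ascending order then
    loci left-to-right.  Excludes the intercept: ``2**(2L) - 1`` components
    for phased models, ``3**L - 1`` for unphased ones."""
    L = len(loci)
    if L < 1:
        raise ValueError("need at least one locus")
    if phased:
        per = [(0, 0), (1, 0), (0, 1), (1, 1)]
    else:
        per = [0, 1, 2]
    keys = [ComponentKey(phased, combo)
            for combo in itertools.product(per, repeat=L)]
    keys = [k for k in keys if not k.is_intercept]
    return sorted(keys, key=ComponentKey.sort_key)


def _locus_effect_parts(locus: LocusSpec, entry, phased: bool) -> list[tuple]:
    """Per-locus allele-index choices for one component entry, in canonical
    order (additive: catalog order; dominance: homozygous pairs first, then
    heterozygous pairs lexicographically)."""
    nb = locus.nonbaseline
    if phased:
        i, j = entry
        if (i, j) == (0, 0):
            return [()]
        if (i, j) == (1, 0):
            return [(s, None) for s in nb]
        if (i, j) == (0, 1):
            return [(None, t) for t in nb]
        return [(s, t) for s in nb for t in nb]
    if entry == 0:
        return [()]
    if entry == 1:
        return [(s,) for s in nb]
    diag = [(s, s) for s in nb]
    off = [(nb[a], nb[b]) for a in range(len(nb)) for b in range(a + 1, len(nb))]
    return diag + off


def effect_labels(component: ComponentKey, loci: Sequence[LocusSpec]
                  ) -> list[EffectLabel]:
    """All coefficients of one component, loci left-to-right (first locus
    varying slowest)."""
    parts = [_locus_effect_parts(loc, e, component.phased)
             for loc, e in zip(loci, component.key)]
    return [EffectLabel(component, tuple(combo))
            for combo in itertools.product(*parts)]


@dataclass
class DesignMatrix:
    """A coded covariate matrix with per-column genetic-component metadata.

    ``labels[0]`` is always the intercept.  ``weights`` are 1 per subject
    row, or the class frequency for genotype-class tables.
    """

    X: np.ndarray
    labels: tuple[EffectLabel, ...]
    loci: tuple[LocusSpec, ...]
    phased: bool
    weights: np.ndarray
    genotypes: pd.DataFrame  # the rows' genotype tokens, one column per locus

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [lab.name(self.loci) for lab in self.labels]

    @property
    def components(self) -> list[ComponentKey]:
        """Distinct non-intercept components, in column order."""
        seen: dict[ComponentKey, None] = {}
        for lab in self.labels:
            if not lab.is_intercept:
                seen.setdefault(lab.component, None)
        return list(seen)

    def columns_of(self, component: ComponentKey) -> np.ndarray:
        return np.array([k for k, lab in enumerate(self.labels)
                         if lab.component == component], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_names)


def _resolve_components(components, loci, phased) -> list[ComponentKey]:
    if isinstance(components, str) and components == "full":
        return enumerate_components(loci, phased)
    keys = []
    for c in components:
        if isinstance(c, ComponentKey):
            if c.phased != phased:
                raise ValueError(f"component {c} has wrong phase flag")
            keys.append(c)
        else:
            keys.append(ComponentKey.from_name(c, loci, phased))
    keys = [k for k in keys if not k.is_intercept]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate components in model spec")
    return sorted(keys, key=ComponentKey.sort_key)


def _extract_rows(data, loci: Sequence[LocusSpec]):
    if isinstance(data, ClassTable):
        gdf = data.genotypes
        weights = np.asarray(data.frequency, dtype=float)
    else:
        gdf = pd.DataFrame(data)
        weights = np.ones(len(gdf))
    missing_ids = [l.locus_id for l in loci if l.locus_id not in gdf.columns]
    if missing_ids:
        raise KeyError(f"genotype columns missing for loci {missing_ids}")
    return gdf[[l.locus_id for l in loci]].reset_index(drop=True), weights


def _locus_atoms(tokens: pd.Series, locus: LocusSpec, phased: bool,
                 star: bool) -> dict[tuple, np.ndarray]:
    """Values of the atomic per-locus coding terms for every row.

    Unphased atoms: ``("w", s)`` and ``("v", s, t)`` with ``s <= t`` in
    catalog order.  Phased atoms: ``("xP", s)`` and ``("xM", t)``.  With
    ``star=True`` the raw inheritance-indicator versions are used instead
    (``w* = allele count``, ``v* = genotype indicator``, ``z`` indicators).
    """
    codes, uniq = pd.factorize(tokens)
    gts = [Genotype.from_token(t) for t in uniq]
    if (codes < 0).any() or any(g.missing for g in gts):
        raise ValueError(f"{locus.locus_id}: missing genotypes must be "
                         "excluded before building a design")
    for g in gts:
        locus.index(g.a1), locus.index(g.a2)
    nb = locus.nonbaseline
    atoms: dict[tuple, np.ndarray] = {}

    if phased:
        if any(not g.phased for g in gts):
            raise PhaseError(f"{locus.locus_id}: phase-known design requested "
                             "on unphased genotypes")
        for side, attr, p in (("xP", "a1", None), ("xM", "a2", None)):
            freqs = locus.p_pat if side == "xP" else locus.p_mat
            for s in nb:
                si = locus.index(s)
                if star:
                    vals = np.array([1.0 if getattr(g, attr) == s else 0.0
                                     for g in gts])
                else:
                    vals = np.array([(1.0 if getattr(g, attr) == s else 0.0)
                                     - freqs[si] for g in gts])
                atoms[(side, s)] = vals[codes]
        return atoms

    if not star and not locus.pooled:
        raise PhaseError(f"{locus.locus_id}: unphased coding requires pooled "
                         "allele frequencies")
    p = {a: (locus.p[locus.index(a)] if not star else 0.0)
         for a in locus.alleles}
    for s in nb:
        if star:
            vals = np.array([float(g.count(s)) for g in gts])
        else:
            cnt = np.array([g.count(s) for g in gts])
            vals = cnt - 2.0 * p[s]
        atoms[("w", s)] = vals[codes]
    for a in range(len(nb)):
        for b in range(a, len(nb)):
            s, t = nb[a], nb[b]
            if star:
                if s == t:
                    vals = np.array([1.0 if (g.a1 == s and g.a2 == s) else 0.0
                                     for g in gts])
                else:
                    vals = np.array(
                        [1.0 if {g.a1, g.a2} == {s, t} else 0.0 for g in gts])
            else:
                vv = []
                for g in gts:
                    xp_s = (g.a1 == s) - p[s]
                    xm_s = (g.a2 == s) - p[s]
                    if s == t:
                        vv.append(xp_s * xm_s)
                    else:
                        xp_t = (g.a1 == t) - p[t]
                        xm_t = (g.a2 == t) - p[t]
                        vv.append(xp_s * xm_t + xp_t * xm_s)
                vals = np.array(vv)
            atoms[("v", s, t)] = vals[codes]
    return atoms


def _label_column(label: EffectLabel, loci, atom_tables, phased, n) -> np.ndarray:
    col = np.ones(n)
    for k, (entry, al) in enumerate(zip(label.component.key, label.alleles)):
        if phased:
            i, j = entry
            if i:
                col = col * atom_tables[k][("xP", al[0])]
            if j:
                col = col * atom_tables[k][("xM", al[1])]
        else:
            if entry == 1:
                col = col * atom_tables[k][("w", al[0])]
            elif entry == 2:
                s, t = sorted(al, key=loci[k].alleles.index)
                col = col * atom_tables[k][("v", s, t)]
    return col


def build_design(data, loci: Sequence[LocusSpec],
                 components="full", phased: bool = False,
                 star: bool = False) -> DesignMatrix:
    """Assemble the GMA design matrix for subject data or a class table.

    Parameters
    ----------
    data : pandas.DataFrame or ClassTable
        Subject-level genotype tokens (one column per locus, no missing
        rows) or a genotype-class summary table.
    loci : sequence of LocusSpec
        Must carry allele frequencies (unless ``star=True``, where coding
        does not use them).
    components : "full" or sequence of ComponentKey / component names
        Reduced models are specified at whole-component granularity; the
        intercept is always included.
    phased : bool
        Build the phase-known (``x_P``/``x_M``) or phase-unknown (``w``/``v``)
        model.
    star : bool
        Use raw inheritance indicators instead of mean-corrected variables
        (the F-infinity coding); see :func:`f_infinity_design`.
    """
    loci = tuple(loci)
    gdf, weights = _extract_rows(data, loci)
    keys = _resolve_components(components, loci, phased)
    atom_tables = [_locus_atoms(gdf[l.locus_id], l, phased, star)
                   for l in loci]
    n = len(gdf)
    labels = [EffectLabel(ComponentKey.intercept(len(loci), phased),
                          tuple([()] * len(loci)))]
    cols = [np.ones(n)]
    for key in keys:
        for lab in effect_labels(key, loci):
            labels.append(lab)
            cols.append(_label_column(lab, loci, atom_tables, phased, n))
    X = np.column_stack(cols)
    return DesignMatrix(X=X, labels=tuple(labels), loci=loci, phased=phased,
                        weights=weights, genotypes=gdf)


def f_infinity_design(data, loci, components="full",
                      phased: bool = False) -> DesignMatrix:
    """Design matrix of the corresponding F-infinity model.

    Columns are built from the raw inheritance indicators (allele counts and
    genotype indicators) rather than their mean-corrected versions.  A
    saturated F-infinity fit reproduces the same fitted genotypic values as
    the saturated GMA fit, but its columns are correlated across orders even
    under Hardy-Weinberg equilibrium, so low-order terms are confounded with
    higher-order ones in reduced models."""
    return build_design(data, loci, components=components, phased=phased,
                        star=True)


def joint_classes(loci: Sequence[LocusSpec], phased: bool) -> pd.DataFrame:
    """Token table of all distinct joint genotype classes (first locus
    varying slowest)."""
    per = [(l.phased_classes() if phased else l.unphased_classes())
           for l in loci]
    rows = [[g.token() for g in combo] for combo in itertools.product(*per)]
    return pd.DataFrame(rows, columns=[l.locus_id for l in loci])
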