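"""Readers and writers for the delimited table and JSON report formats.

Genotype token dialect (mirrors the VCF ``GT`` separator convention, though
files are plain TSV/CSV): phased ``A|B`` with the paternal allele first,
unphased ``A/B``, missing ``.``.  Allele labels are arbitrary strings not
containing the separator characters.

A genotype-class table has one or more genotype columns (named by locus),
then a ``frequency`` column, then one column per trait mean.  The packaged
``acp1.tsv`` fixture is the published human acid phosphatase (ACP1)
three-allele table: six unphased genotype classes with observed frequencies
and expected genotypic values for the enzyme-activity and
enzyme-inhibition traits.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import ClassTable, LocusSpec

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "read_class_table",
    "write_class_table",
    "write_report",
    "load_acp1",
]

FREQUENCY_COL = "frequency"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject-level table (one row per subject; genotype token
    columns named by locus, plus phenotype/covariate columns)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_class_table(path) -> ClassTable:
    """Read a genotype-class table: genotype columns, then ``frequency``,
    then trait-mean columns."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if FREQUENCY_COL not in df.columns:
        raise ValueError(f"class table needs a {FREQUENCY_COL!r} column")
    cut = list(df.columns).index(FREQUENCY_COL)
    if cut == 0:
        raise ValueError("class table needs at least one genotype column")
    gcols = list(df.columns[:cut])
    tcols = list(df.columns[cut + 1:])
    return ClassTable(
        genotypes=df[gcols].astype(str),
        frequency=df[FREQUENCY_COL].to_numpy(dtype=float),
        traits=df[tcols].astype(float) if tcols else None,
    )


def write_class_table(table: ClassTable, path) -> None:
    df = table.genotypes.copy()
    df[FREQUENCY_COL] = table.frequency
    if table.traits is not None:
        for c in table.traits.columns:
            df[c] = table.traits[c].to_numpy()
    df.to_csv(path, sep=_sep_for(path), index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_report(result, path) -> None:
    """Serialize a results object (anything with ``to_dict``, or a plain
    mapping) to pretty-printed JSON."""
    payload = result.to_dict() if hasattr(result, "to_dict") else result
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, cls=_ReportEncoder)
        + "\n")


def load_acp1() -> tuple[ClassTable, LocusSpec]:
    """The packaged ACP1 class table and its locus specification.

    Returns the six-class table (traits ``activity`` and ``inhibition``)
    and a ``LocusSpec`` with catalog (A, B, C), baseline C and pooled
    allele frequencies gene-counted from the observed class frequencies.
    The published class frequencies sum to 0.9999 (round-off); they are
    used as-is, so the estimated allele frequencies reproduce the published
    0.3534 / 0.5818 / 0.0647 exactly."""
    from .coding import estimate_allele_freqs

    ref = resources.files("gma").joinpath("data/acp1.tsv")
    with resources.as_file(ref) as path:
        table = read_class_table(path)
    locus = LocusSpec("acp1", ("A", "B", "C"), baseline="C")
    p = estimate_allele_freqs(table.genotypes["acp1"], locus,
                              weights=table.frequency)
    return table, locus.with_freqs(pooled=p)
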