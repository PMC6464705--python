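"""Insertion presence/absence genotype summaries.

Genotypes are diploid insertion states per locus and individual, coded
``00`` (homozygous absent), ``10`` (heterozygous), ``11`` (homozygous
present) or ``NA`` (missing, e.g. a failed PCR).  Missing genotypes are a
first-class state and are excluded from every denominator; Hardy-Weinberg
equilibrium is never assumed.

The module classifies loci as fixed present / fixed absent / polymorphic,
computes insertion allele frequencies, tallies panels per species, and finds
group-diagnostic loci: loci where two labelled groups of individuals (e.g.
red-necked vs gray-necked owl monkeys) are reciprocally fixed for presence
and absence.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .formats import read_tsv, write_tsv

VALID_GENOTYPES = ("00", "10", "11", "NA")


@dataclass
class GenotypeTable:
    """Loci x individuals genotype grid plus per-individual metadata.

    ``data``: DataFrame indexed by locus_id, columns are individual ids,
    cells in ``{00, 10, 11, NA}``.  ``meta``: DataFrame indexed by individual
    with at least a ``species`` column and optionally a ``group`` column;
    group labels must cover all individuals or none.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        bad = set(self.data.to_numpy().ravel()) - set(VALID_GENOTYPES)
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if not self.meta.empty:
            missing = set(self.data.columns) - set(self.meta.index)
            if missing:
                raise ValueError(f"individuals without metadata: {sorted(missing)}")
            if "group" in self.meta.columns:
                labelled = self.meta.loc[list(self.data.columns), "group"].notna()
                if labelled.any() and not labelled.all():
                    raise ValueError("group labels must cover all individuals or none")

    @classmethod
    def read(cls, table_path: str | os.PathLike, meta_path: str | os.PathLike | None = None):
        data = read_tsv(table_path, index_col=0, dtype=str).fillna("NA")
        meta = (
            read_tsv(meta_path, index_col=0, dtype=str)
            if meta_path is not None
            else pd.DataFrame()
        )
        return cls(data=data, meta=meta)

    def write(self, table_path: str | os.PathLike, meta_path: str | os.PathLike | None = None):
        write_tsv(self.data, table_path, index=True)
        if meta_path is not None and not self.meta.empty:
            write_tsv(self.meta, meta_path, index=True)


@dataclass(frozen=True)
class LocusSummary:
    locus_id: str
    label: str               # fixed_present / fixed_absent / polymorphic / unclassified
    frequency: float | None  # insertion allele frequency among non-missing
    n_called: int
    n11: int
    n10: int
    n00: int


def classify_locus(genotypes: Mapping[str, str] | pd.Series, locus_id: str = "") -> LocusSummary:
    """Fixation state and insertion allele frequency for one locus.

    ``fixed_present`` requires every non-missing genotype to be ``11``;
    ``fixed_absent`` requires all ``00``; anything mixed is ``polymorphic``.
    Frequency is ``(2*n11 + n10) / (2 * non-missing)``.  All-missing loci are
    ``unclassified`` (with a warning) and carry no frequency.
    """
    s = pd.Series(genotypes, dtype=str)
    if isinstance(genotypes, pd.Series) and not locus_id:
        locus_id = str(genotypes.name)
    n11 = int((s == "11").sum())
    n10 = int((s == "10").sum())
    n00 = int((s == "00").sum())
    n = n11 + n10 + n00
    if n == 0:
        warnings.warn(f"locus {locus_id!r}: all genotypes missing")
        return LocusSummary(locus_id, "unclassified", None, 0, 0, 0, 0)
    freq = (2 * n11 + n10) / (2 * n)
    if n11 == n:
        label = "fixed_present"
    elif n00 == n:
        label = "fixed_absent"
    else:
        label = "polymorphic"
    return LocusSummary(locus_id, label, freq, n, n11, n10, n00)


def classify_all(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus classification table (locus order preserved)."""
    rows = [
        classify_locus(table.data.loc[locus], str(locus)).__dict__
        for locus in table.data.index
    ]
    return pd.DataFrame(rows).set_index("locus_id")


def find_group_diagnostic_loci(
    table: GenotypeTable, min_informative: int = 2
) -> pd.DataFrame:
    """Loci where two groups are reciprocally fixed for presence/absence.

    A locus qualifies when every non-missing individual of one group is
    ``11`` and every non-missing individual of the other group is ``00``,
    with at least ``min_informative`` non-missing individuals per group.
    Missing genotypes are ignored.  Requires exactly two group labels.
    Returns a DataFrame (locus_id, present_group, absent_group).
    """
    if table.meta.empty or "group" not in table.meta.columns:
        raise ValueError("group labels required")
    groups = table.meta.loc[list(table.data.columns), "group"]
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    g1, g2 = labels
    rows = []
    for locus in table.data.index:
        s = table.data.loc[locus]
        byg = {}
        ok = True
        for g in (g1, g2):
            vals = s[groups[groups == g].index]
            called = vals[vals != "NA"]
            if len(called) < min_informative:
                ok = False
                break
            if (called == "11").all():
                byg[g] = "present"
            elif (called == "00").all():
                byg[g] = "absent"
            else:
                ok = False
                break
        if ok and set(byg.values()) == {"present", "absent"}:
            present = g1 if byg[g1] == "present" else g2
            absent = g2 if present == g1 else g1
            rows.append((str(locus), present, absent))
    return pd.DataFrame(rows, columns=["locus_id", "present_group", "absent_group"])


def summarize_panel(table: GenotypeTable) -> pd.DataFrame:
    """Fixed/polymorphic locus tallies per species and pooled.

    For each species the classification uses only that species' individuals;
    the ``all`` row pools every individual.  Row order is deterministic
    (species sorted, pooled row last).
    """
    if table.data.empty:
        return pd.DataFrame(
            [("all", 0, 0, 0, 0, 0)],
            columns=["species", "n_loci", "fixed_present", "fixed_absent", "polymorphic",
                     "unclassified"],
        )
    species_of = (
        table.meta.loc[list(table.data.columns), "species"]
        if not table.meta.empty and "species" in table.meta.columns
        else pd.Series("all", index=table.data.columns)
    )
    rows = []
    groups = [(sp, list(idx.index)) for sp, idx in species_of.groupby(species_of)]
    groups.sort(key=lambda t: t[0])
    groups.append(("all", list(table.data.columns)))
    for sp, individuals in groups:
        counts = {"fixed_present": 0, "fixed_absent": 0, "polymorphic": 0, "unclassified": 0}
        for locus in table.data.index:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary = classify_locus(table.data.loc[locus, individuals], str(locus))
            counts[summary.label] += 1
        rows.append((sp, len(table.data.index), *counts.values()))
    return pd.DataFrame(
        rows,
        columns=["species", "n_loci", "fixed_present", "fixed_absent", "polymorphic",
                 "unclassified"],
    )
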