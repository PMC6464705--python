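"""Full-length element filtering, flanked-locus extraction and age estimation.

A copy is *full length* when its alignment to the subfamily consensus starts
within the first ``max_start`` (default 4) consensus bases and ends no more
than 2 bases short of the last pre-tail consensus position.  In 1-based
consensus coordinates with the tail beginning at ``a_tail_start``::

    cons_begin <= max_start  and  cons_end >= (a_tail_start - 1) - 2

Ages follow the molecular-clock relation ``T = D / t`` with ``D`` the copy's
divergence from its subfamily consensus expressed as a proportion and ``t``
the substitution rate per base per Myr.  The default rate, 0.006024/bp/Myr,
is a composite Platyrrhine/Cebidae neutral rate; at that rate a single
substitution in a ~100 bp element (1% divergence) corresponds to ~1.66 Myr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GenomeRecord
from .scanner import ConfigurationError, ConsensusLibrary, ElementHit

DEFAULT_RATE = 0.006024  # substitutions per base per Myr
DEFAULT_FLANK = 600


@dataclass
class FullLengthElement:
    """A full-length hit with its flanking sequence and locus identity."""

    hit: ElementHit
    flank5: str
    flank3: str
    locus_id: str
    element_seq: str = ""  # genomic sequence of the consensus-aligned body + tail

    @property
    def element_len(self) -> int:
        return self.hit.end - self.hit.start

    @property
    def filled_inner_len(self) -> int:
        """Distance between the flank extraction points on the filled allele."""
        return self.element_len + self.hit.a_tail_len


@dataclass(frozen=True)
class AgeEstimate:
    D: float  # divergence as a proportion
    t: float  # substitution rate per base per Myr
    T: float  # age in Myr

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("age must be non-negative")


def is_full_length(hit: ElementHit, a_tail_start: int, max_start: int = 4) -> bool:
    last_pre_tail = a_tail_start - 1
    return hit.cons_begin <= max_start and hit.cons_end >= last_pre_tail - 2


def filter_full_length(
    hits: Iterable[ElementHit],
    library: ConsensusLibrary,
    genomes: Mapping[str, Mapping[str, str]] | None = None,
    flank: int = DEFAULT_FLANK,
    max_start: int = 4,
) -> list[FullLengthElement]:
    """Keep full-length hits and attach ``flank`` bp of sequence on each side.

    ``genomes`` maps genome_id -> contig_id -> sequence; when omitted, flanks
    are left empty (the filter itself needs only consensus coordinates).
    Flanks are truncated (with a warning) at contig edges.  The operation is
    idempotent and independent of input order; output is sorted by locus.
    """
    out: list[FullLengthElement] = []
    for hit in hits:
        if hit.subfamily not in library.entries:
            raise ConfigurationError(f"subfamily {hit.subfamily!r} not in library")
        if not is_full_length(hit, library.a_tail_start[hit.subfamily], max_start):
            continue
        flank5 = flank3 = ""
        element_seq = ""
        if genomes is not None:
            seq = genomes[hit.genome_id][hit.contig_id]
            es, ee = hit.span_with_tail
            lo = max(0, es - flank)
            hi = min(len(seq), ee + flank)
            if lo > es - flank or hi < ee + flank:
                warnings.warn(
                    f"flank truncated at contig edge for {hit.genome_id}:{hit.contig_id}:{es}"
                )
            flank5 = seq[lo:es]
            flank3 = seq[ee:hi]
            element_seq = seq[es:ee]
        locus_id = f"{hit.genome_id}.{hit.contig_id}.{hit.start}"
        out.append(
            FullLengthElement(
                hit=hit, flank5=flank5, flank3=flank3, locus_id=locus_id,
                element_seq=element_seq,
            )
        )
    out.sort(key=lambda e: (e.hit.genome_id, e.hit.contig_id, e.hit.start))
    dedup: dict[str, FullLengthElement] = {}
    for e in out:
        dedup[e.locus_id] = e
    return list(dedup.values())


def estimate_age(perc_div: float, rate: float = DEFAULT_RATE) -> AgeEstimate:
    """Age of an insertion from its percent divergence, via ``T = D / t``."""
    if perc_div < 0:
        raise ValueError("negative divergence")
    if rate <= 0:
        raise ValueError("rate must be positive")
    D = perc_div / 100.0
    return AgeEstimate(D=D, t=rate, T=D / rate)


@dataclass
class AgeSummary:
    table: pd.DataFrame  # per group: n, mean_age, min_age, max_age (Myr, 1 dp)
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (counts, bin_edges)


def summarize_ages(
    elements: Sequence[FullLengthElement] | Sequence[ElementHit],
    grouping: str = "subfamily",
    rate: float = DEFAULT_RATE,
    bin_width: float = 1.0,
) -> AgeSummary:
    """Per-group age statistics and divergence histograms.

    ``grouping`` is an :class:`ElementHit` attribute name (``subfamily`` or
    ``genome_id``).  Ages are reported to 1 decimal Myr; histogram bins are
    ``bin_width`` percentage points of divergence wide.  Empty groups are
    omitted with a warning.
    """
    rows = []
    for el in elements:
        hit = el.hit if isinstance(el, FullLengthElement) else el
        rows.append((getattr(hit, grouping), hit.perc_div, estimate_age(hit.perc_div, rate).T))
    if not rows:
        warnings.warn("no elements to summarize")
        return AgeSummary(
            table=pd.DataFrame(columns=["group", "n", "mean_age", "min_age", "max_age"]),
            histograms={},
        )
    df = pd.DataFrame(rows, columns=["group", "perc_div", "age"])
    agg = (
        df.groupby("group", sort=True)["age"]
        .agg(n="size", mean_age="mean", min_age="min", max_age="max")
        .round({"mean_age": 1, "min_age": 1, "max_age": 1})
        .reset_index()
    )
    hists = {}
    max_div = max(1.0, float(np.ceil(df["perc_div"].max())))
    edges = np.arange(0.0, max_div + bin_width, bin_width)
    for grp, sub in df.groupby("group", sort=True):
        counts, _ = np.histogram(sub["perc_div"].to_numpy(), bins=edges)
        hists[str(grp)] = (counts, edges)
    return AgeSummary(table=agg, histograms=hists)


def ages_table(
    elements: Sequence[FullLengthElement], rate: float = DEFAULT_RATE
) -> pd.DataFrame:
    """TSV-ready per-locus table: locus_id, subfamily, perc_div, age (Myr)."""
    rows = [
        (
            e.locus_id,
            e.hit.subfamily,
            round(e.hit.perc_div, 1),
            round(estimate_age(e.hit.perc_div, rate).T, 1),
        )
        for e in elements
    ]
    return pd.DataFrame(rows, columns=["locus_id", "subfamily", "perc_div", "age_myr"])
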