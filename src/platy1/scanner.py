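"""Detect copies of consensus library entries in genome sequence.

This is a desk-scale repeat annotator: exact k-mer seeding followed by full
Smith-Waterman alignment of the consensus against a window around each seed
cluster, with one-annotation-per-locus overlap resolution (highest score wins,
ties broken by library order).  Each accepted hit is annotated with the two
target-primed reverse transcription hallmarks that survive in genomic
sequence: the 3' A-rich tail and the flanking target site duplication (TSD).

Percent divergence of a copy from its consensus is the fraction of mismatched
aligned columns, excluding gap columns and columns that fall in the
consensus's own A-tail region (A-tail length variation is not substitution
divergence).  No CpG or multiple-hit correction is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .align import KmerIndex, LocalAlignment, Scoring, cluster_seeds, smith_waterman
from .formats import GenomeRecord, RepeatAnnotationRow, read_fasta, revcomp


class ConfigurationError(ValueError):
    pass


class DivergenceUndefinedError(ValueError):
    """Raised when an alignment has no aligned (non-gap, non-tail) columns."""


def _auto_tail_start(seq: str, min_run: int = 5, min_frac: float = 0.8) -> int:
    """1-based position where a terminal A-rich run begins, or len+1 if none.

    The run is the longest suffix with >= ``min_frac`` A content, at least
    ``min_run`` long, and starting on an A.
    """
    n = len(seq)
    best = 0
    a = 0
    for i in range(n - 1, -1, -1):
        ln = n - i
        if seq[i] == "A":
            a += 1
            if a / ln >= min_frac and ln >= min_run:
                best = ln
    return n - best + 1


@dataclass
class ConsensusLibrary:
    """Named consensus sequences plus the start of each one's A-tail region.

    ``a_tail_start`` is 1-based on the consensus; ``len(consensus) + 1`` means
    the consensus carries no tail (the tail is appended at insertion time and
    is never part of the alignable body).
    """

    entries: dict[str, str]
    a_tail_start: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("empty consensus library")
        for name, seq in self.entries.items():
            if len(seq) < 50:
                raise ConfigurationError(f"consensus {name!r} shorter than 50 bp")
            ts = self.a_tail_start.setdefault(name, _auto_tail_start(seq))
            if not 1 <= ts <= len(seq) + 1:
                raise ConfigurationError(f"a_tail_start out of range for {name!r}")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ConsensusLibrary":
        recs = read_fasta(path)
        return cls({r.contig_id: r.sequence for r in recs})

    @property
    def order(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class ScanParams:
    k: int = 11
    min_score: int = 30
    scoring: Scoring = Scoring()
    seed_band: int = 16
    window_pad: int = 24
    overlap_frac: float = 0.5
    tsd_min: int = 5
    tsd_max: int = 25
    a_tail_min_frac: float = 0.8
    a_tail_max_len: int = 80
    end_completion: int = 4


@dataclass(frozen=True)
class TSDAnnotation:
    left: tuple[int, int]   # 0-based half-open genomic interval
    right: tuple[int, int]
    sequence: str


@dataclass
class ElementHit:
    """One detected element copy.

    ``start``/``end`` are the 0-based half-open genomic span of the
    consensus-aligned body (A-tail excluded); ``cons_begin``/``cons_end`` are
    1-based inclusive on the consensus.  ``a_tail_len`` counts the A-rich run
    immediately 3' of the body (5' T-run for minus-strand copies).
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    subfamily: str
    cons_begin: int
    cons_end: int
    perc_div: float
    score: int
    tsd: TSDAnnotation | None = None
    a_tail_len: int = 0
    alignment: LocalAlignment | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must be < end")
        if self.cons_begin > self.cons_end:
            raise ValueError("cons_begin must be <= cons_end")
        if not 0.0 <= self.perc_div <= 100.0:
            raise ValueError("perc_div out of [0, 100]")
        if self.tsd is not None and len(self.tsd.sequence) == 0:
            raise ValueError("empty TSD sequence")

    @property
    def span_with_tail(self) -> tuple[int, int]:
        """Genomic span including the A-tail (oriented by strand)."""
        if self.strand == "+":
            return self.start, self.end + self.a_tail_len
        return self.start - self.a_tail_len, self.end

    def to_out_row(self) -> RepeatAnnotationRow:
        cons_len_left = 0  # unknown here; filled by caller if needed
        return RepeatAnnotationRow(
            score=self.score,
            perc_div=round(self.perc_div, 1),
            perc_del=0.0,
            perc_ins=0.0,
            query_contig=self.contig_id,
            query_begin=self.start + 1,
            query_end=self.end,
            strand=self.strand,
            repeat_name=self.subfamily,
            repeat_class="SINE/Platy",
            repeat_begin=self.cons_begin,
            repeat_end=self.cons_end,
            repeat_left=cons_len_left,
        )


def compute_divergence(
    alignment: LocalAlignment,
    a_tail_start: int,
    cons_offset: int = 0,
    extra_pairs: Iterable[tuple[str, str]] = (),
) -> float:
    """Percent mismatch over aligned columns, excluding gaps and tail columns.

    ``alignment`` must have the consensus as query.  ``cons_offset`` shifts
    query coordinates to 1-based consensus positions (0 when the query is the
    full consensus).  ``N`` in either row counts as a mismatch.
    ``extra_pairs`` adds (consensus base, genome base) columns from
    end-completion (see :func:`_end_completion_pairs`); local alignment trims
    substituted terminal bases, which would otherwise bias divergence (and
    the ages derived from it) downward.
    """
    cons_pos = alignment.q_start + cons_offset  # becomes 1-based after increment
    aligned = 0
    mism = 0
    for qc, rc in zip(alignment.q_aln, alignment.r_aln):
        if qc != "-":
            cons_pos += 1
        if qc == "-" or rc == "-":
            continue
        if cons_pos >= a_tail_start:
            continue
        aligned += 1
        if qc != rc or qc == "N":
            mism += 1
    for qc, rc in extra_pairs:
        aligned += 1
        if qc != rc or qc == "N" or rc == "N":
            mism += 1
    if aligned == 0:
        raise DivergenceUndefinedError("alignment has no aligned non-tail columns")
    return 100.0 * mism / aligned


def _end_completion_pairs(
    aln: LocalAlignment,
    cons: str,
    oriented: str,
    window_start: int,
    a_tail_start: int,
    max_ext: int,
) -> list[tuple[str, str]]:
    """(consensus, genome) base pairs completing the alignment to the
    consensus ends.

    When the local alignment stops within ``max_ext`` bases of a consensus
    end (the pre-tail end on the 3' side), the skipped consensus bases are
    paired ungapped with the adjacent genome bases so that terminal
    substitutions still count toward divergence.  The reported alignment
    interval and score are left untouched.
    """
    pairs: list[tuple[str, str]] = []
    o_start = window_start + aln.r_start
    o_end = window_start + aln.r_end
    lead = aln.q_start
    if 0 < lead <= max_ext and o_start - lead >= 0:
        pairs.extend(zip(cons[:lead], oriented[o_start - lead : o_start]))
    body_end = min(len(cons), a_tail_start - 1)  # last 1-based pre-tail position
    trail = body_end - aln.q_end
    if 0 < trail <= max_ext and o_end + trail <= len(oriented):
        pairs.extend(zip(cons[aln.q_end : body_end], oriented[o_end : o_end + trail]))
    return pairs


def detect_a_tail(
    contig_seq: str,
    start: int,
    end: int,
    strand: str,
    min_frac: float = 0.8,
    max_len: int = 80,
) -> int:
    """Length of the maximal A-rich run at the element's 3' end.

    For ``+`` hits the run begins at ``end`` and consists of As; for ``-``
    hits the complement (a T-run ending at ``start``) is measured.  A run
    qualifies while its A fraction stays >= ``min_frac``; the run must end on
    the tail base itself.
    """
    if strand == "+":
        region = contig_seq[end : end + max_len]
        base = "A"
    else:
        region = contig_seq[max(0, start - max_len) : start][::-1]
        base = "T"
    best = 0
    hits = 0
    for i, ch in enumerate(region):
        if ch == base:
            hits += 1
            if hits / (i + 1) >= min_frac:
                best = i + 1
    return best


def detect_tsd(
    contig_seq: str,
    span_start: int,
    span_end: int,
    tsd_min: int = 5,
    tsd_max: int = 25,
) -> TSDAnnotation | None:
    """Longest exact target-site duplication flanking ``[span_start, span_end)``.

    The left copy ends at the insertion 5' boundary and the right copy begins
    immediately after the 3' boundary (past the A-tail, which the caller must
    include in the span).  Returns ``None`` when no duplication of length in
    ``[tsd_min, tsd_max]`` exists.
    """
    hi = min(tsd_max, span_start, len(contig_seq) - span_end)
    for L in range(hi, tsd_min - 1, -1):
        left = contig_seq[span_start - L : span_start]
        if "N" in left:
            continue
        if left == contig_seq[span_end : span_end + L]:
            return TSDAnnotation(
                left=(span_start - L, span_start),
                right=(span_end, span_end + L),
                sequence=left,
            )
    return None


def detect_tsd_jittered(
    contig_seq: str,
    span_start: int,
    span_end: int,
    strand: str,
    tsd_min: int = 5,
    tsd_max: int = 25,
    jitter: int = 3,
) -> TSDAnnotation | None:
    """TSD search tolerating uncertainty in the A-tail-side boundary.

    The tail-side span boundary depends on the measured A-tail length, which
    can over- or under-shoot by a base or two when the flank starts with As;
    the boundary on that side is jittered by up to ``jitter`` bases and the
    first (longest, least-shifted) duplication wins.
    """
    for d in sorted(range(-jitter, jitter + 1), key=abs):
        if strand == "+":
            ann = detect_tsd(contig_seq, span_start, span_end + d, tsd_min, tsd_max)
        else:
            ann = detect_tsd(contig_seq, span_start + d, span_end, tsd_min, tsd_max)
        if ann is not None:
            return ann
    return None


def _candidates_for_orientation(
    target: str,
    index: KmerIndex,
    cons: str,
    params: ScanParams,
) -> list[tuple[int, LocalAlignment]]:
    """(window_start, alignment) candidates of one consensus vs one oriented contig."""
    seeds = index.seeds(cons)
    out = []
    for d_lo, d_hi, p_lo, p_hi, _n in cluster_seeds(
        seeds, band=params.seed_band, max_gap=2 * len(cons)
    ):
        ws = max(0, p_lo - len(cons) - params.window_pad)
        we = min(len(target), p_hi + params.k + len(cons) + params.window_pad)
        aln = smith_waterman(cons, target[ws:we], params.scoring)
        if aln is not None and aln.score >= params.min_score:
            out.append((ws, aln))
    return out


def scan_genome(
    genome: Iterable[GenomeRecord] | GenomeRecord,
    library: ConsensusLibrary,
    params: ScanParams = ScanParams(),
) -> list[ElementHit]:
    """Find all library-entry copies in the given contigs.

    Both strands of every contig are scanned against every library entry;
    overlapping candidates (overlap > ``overlap_frac`` of the shorter span)
    are resolved to the single highest-scoring entry, ties broken first by
    library order, then by position.  Output is sorted by
    (genome, contig, start).
    """
    if isinstance(genome, GenomeRecord):
        genome = [genome]
    order = {name: i for i, name in enumerate(library.order)}
    hits: list[ElementHit] = []
    for rec in genome:
        fwd = rec.sequence
        rc = revcomp(fwd)
        L = len(fwd)
        raw: list[tuple[int, int, int, str, str, LocalAlignment, list]] = []
        for oriented, strand in ((fwd, "+"), (rc, "-")):
            index = KmerIndex(oriented, params.k)
            for name, cons in library.entries.items():
                for ws, aln in _candidates_for_orientation(oriented, index, cons, params):
                    o_start = ws + aln.r_start
                    o_end = ws + aln.r_end
                    if strand == "+":
                        g_start, g_end = o_start, o_end
                    else:
                        g_start, g_end = L - o_end, L - o_start
                    extra = _end_completion_pairs(
                        aln, cons, oriented, ws, library.a_tail_start[name],
                        params.end_completion,
                    )
                    raw.append((g_start, g_end, aln.score, strand, name, aln, extra))
        # one annotation per locus: highest score, then library order, then position
        raw.sort(key=lambda t: (-t[2], order[t[4]], t[0]))
        kept: list[tuple[int, int, int, str, str, LocalAlignment, list]] = []
        for cand in raw:
            s, e = cand[0], cand[1]
            overlap_hit = False
            for k in kept:
                ov = min(e, k[1]) - max(s, k[0])
                if ov > params.overlap_frac * min(e - s, k[1] - k[0]):
                    overlap_hit = True
                    break
            if not overlap_hit:
                kept.append(cand)
        for g_start, g_end, score, strand, name, aln, extra in kept:
            tail_start = library.a_tail_start[name]
            hit = ElementHit(
                genome_id=rec.genome_id,
                contig_id=rec.contig_id,
                start=g_start,
                end=g_end,
                strand=strand,
                subfamily=name,
                cons_begin=aln.q_start + 1,
                cons_end=aln.q_end,
                perc_div=compute_divergence(aln, tail_start, extra_pairs=extra),
                score=score,
                alignment=aln,
            )
            hit.a_tail_len = detect_a_tail(
                fwd, g_start, g_end, strand, params.a_tail_min_frac, params.a_tail_max_len
            )
            ss, se = hit.span_with_tail
            hit.tsd = detect_tsd_jittered(
                fwd, ss, se, strand, params.tsd_min, params.tsd_max
            )
            hits.append(hit)
    hits.sort(key=lambda h: (h.genome_id, h.contig_id, h.start))
    return hits


def annotate_hit(
    contig_seq: str, hit: ElementHit, params: ScanParams = ScanParams()
) -> ElementHit:
    """Recompute the TSD and A-tail annotations of a hit on its contig."""
    tail = detect_a_tail(
        contig_seq, hit.start, hit.end, hit.strand, params.a_tail_min_frac, params.a_tail_max_len
    )
    hit = replace(hit, a_tail_len=tail)
    ss, se = hit.span_with_tail
    hit.tsd = detect_tsd_jittered(
        contig_seq, ss, se, hit.strand, params.tsd_min, params.tsd_max
    )
    return hit
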