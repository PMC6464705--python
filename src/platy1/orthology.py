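"""Per-locus, per-genome presence/absence calling by flank anchoring.

For each full-length locus the two 600 bp flanks are anchored in a target
genome by seeded, banded local alignment.  When both flanks anchor on the
same contig in the same orientation, the span between the inner anchor ends
is examined:

* **present** - the inter-anchor span contains sequence covering >= 50% of
  the element at >= 75% identity to it;
* **absent**  - the span is consistent with the pre-insertion (empty) allele:
  the apparent deletion relative to the filled allele falls within
  ``[0.8 x element_length, element_length + TSD + A-tail + 20]``.  At an
  empty site the two flank anchors overlap by one target-site-duplication
  copy, so the observed deletion is approximately element + tail + TSD;
* **unresolved** - anchoring failed, anchors disagree in contig/orientation,
  or the span is >= 20% N.  Unresolved is a first-class state: assembly gaps
  must not be silently converted into absence calls.

Loci are then classified from the per-genome states: lineage-specific to a
genome (present there, absent everywhere else), shared by a subset, or shared
by all genomes; any unresolved cell puts the locus in an explicit unresolved
bucket rather than dropping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import KmerIndex, LocalAlignment, Scoring, cluster_seeds, smith_waterman
from .catalog import FullLengthElement
from .formats import GenomeRecord, revcomp


@dataclass(frozen=True)
class OrthologyParams:
    k: int = 11
    min_anchor: int = 100          # flanks shorter than this cannot anchor
    min_cluster_seeds: int = 3
    max_anchor_candidates: int = 8
    anchor_accept_frac: float = 0.45  # score per query base ending the candidate search
    min_anchor_score: int = 60
    band: int = 48
    seed_band: int = 24
    inner_anchor_len: int = 120    # fallback re-anchor length at the inner flank end
    max_inner_trim: int = 40       # tolerated unanchored bases at the inner flank end
    present_min_cov: float = 0.5
    present_min_ident: float = 0.75
    gap_low_frac: float = 0.8      # lower deletion bound, x element length
    gap_pad: int = 20              # upper deletion bound slack, bp
    max_n_frac: float = 0.2
    tsd_max: int = 25
    scoring: Scoring = Scoring()


@dataclass
class OrthologyCall:
    locus_id: str
    genome_id: str
    state: str                      # present / absent / unresolved
    gap_len: int | None = None      # observed deletion vs the filled allele, bp
    flank5_identity: float | None = None
    flank3_identity: float | None = None
    reason: str = ""


class GenomeIndex:
    """K-mer indexes of every contig of a genome, both orientations.

    Build once per genome and reuse across loci; anchoring hundreds of flanks
    against a fresh index would dominate the run time otherwise.
    """

    def __init__(self, records: Iterable[GenomeRecord], k: int = 11):
        self.k = k
        self.contigs: dict[str, str] = {}
        self.genome_id = ""
        self._idx: dict[tuple[str, str], KmerIndex] = {}
        for rec in records:
            self.genome_id = rec.genome_id
            self.contigs[rec.contig_id] = rec.sequence
            self._idx[(rec.contig_id, "+")] = KmerIndex(rec.sequence, k)
            self._idx[(rec.contig_id, "-")] = KmerIndex(revcomp(rec.sequence), k)

    def oriented(self, contig_id: str, strand: str) -> str:
        seq = self.contigs[contig_id]
        return seq if strand == "+" else revcomp(seq)

    def items(self):
        return self._idx.items()


def _best_anchor(
    query: str, index: GenomeIndex, params: OrthologyParams
) -> tuple[str, str, LocalAlignment] | None:
    """Best local alignment of ``query`` across all contigs/orientations."""
    best: tuple[int, str, str, LocalAlignment] | None = None
    candidates: list[tuple[int, str, str, int, int]] = []
    for (contig_id, strand), kidx in index.items():
        seeds = kidx.seeds(query)
        for d_lo, d_hi, p_lo, p_hi, n in cluster_seeds(
            seeds, band=params.seed_band, max_gap=2 * len(query)
        ):
            if n < params.min_cluster_seeds:
                continue
            candidates.append((n, contig_id, strand, (d_lo + d_hi) // 2, d_hi - d_lo))
    # flanks containing repeat copies seed decoy clusters at every other copy
    # of that repeat; rank clusters by seed support and align only the top few
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accept = params.anchor_accept_frac * len(query)
    for n, contig_id, strand, diag, spread in candidates[: params.max_anchor_candidates]:
        kidx = index._idx[(contig_id, strand)]
        aln = smith_waterman(
            query, kidx.seq, params.scoring, diag=diag, band=params.band + spread
        )
        if aln is None or aln.score < params.min_anchor_score:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, contig_id, strand, aln)
        if best[0] >= accept:
            break  # unambiguous anchor; lower-support candidates cannot do better
    if best is None:
        return None
    return best[1], best[2], best[3]


def _project_inner_end(
    flank: str, which: str, index: GenomeIndex, params: OrthologyParams
) -> tuple[str, str, int, float] | None:
    """Anchor a flank and project its element-side end into the target.

    ``which`` is ``"5"`` (inner end = flank 3' end) or ``"3"`` (inner end =
    flank 5' start).  Returns (contig, strand, projected position in the
    oriented frame, identity) or ``None`` when anchoring fails.  If the best
    local alignment does not reach within ``max_inner_trim`` of the inner end
    (e.g. a target-specific insertion interrupts the flank), the terminal
    ``inner_anchor_len`` bases are re-anchored on their own.
    """
    if len(flank) < params.min_anchor:
        return None
    hit = _best_anchor(flank, index, params)
    if hit is None:
        return None
    contig, strand, aln = hit
    offset = 0
    if which == "5":
        trim = len(flank) - aln.q_end
    else:
        trim = aln.q_start
    if trim > params.max_inner_trim:
        sub = flank[-params.inner_anchor_len :] if which == "5" else flank[: params.inner_anchor_len]
        offset = len(flank) - len(sub) if which == "5" else 0
        hit = _best_anchor(sub, index, params)
        if hit is None:
            return None
        contig, strand, aln = hit
        flank = sub
        if which == "5":
            trim = len(flank) - aln.q_end
        else:
            trim = aln.q_start
        if trim > params.max_inner_trim:
            return None
    if which == "5":
        pos = aln.r_end + (len(flank) - aln.q_end)  # extrapolate over trimmed tail
    else:
        pos = aln.r_start - aln.q_start
    return contig, strand, pos, aln.identity


def call_orthologous_state(
    locus: FullLengthElement,
    target: GenomeIndex | Iterable[GenomeRecord],
    params: OrthologyParams = OrthologyParams(),
) -> OrthologyCall:
    """Decide whether ``locus`` is present, absent or unresolved in ``target``."""
    index = target if isinstance(target, GenomeIndex) else GenomeIndex(list(target), params.k)
    gid = index.genome_id

    def unresolved(reason: str) -> OrthologyCall:
        return OrthologyCall(locus.locus_id, gid, "unresolved", reason=reason)

    if len(locus.flank5) < params.min_anchor or len(locus.flank3) < params.min_anchor:
        return unresolved("flank shorter than min_anchor")
    a5 = _project_inner_end(locus.flank5, "5", index, params)
    a3 = _project_inner_end(locus.flank3, "3", index, params)
    if a5 is None or a3 is None:
        return unresolved("flank anchoring failed")
    c5, s5, t5, id5 = a5
    c3, s3, t3, id3 = a3
    if c5 != c3 or s5 != s3:
        return unresolved("anchors disagree in contig or orientation")
    span = t3 - t5
    max_span = locus.filled_inner_len + params.tsd_max + params.gap_pad + params.band
    if span < -(params.tsd_max + params.gap_pad) or span > max_span:
        return unresolved("anchors not collinear")
    oriented = index.oriented(c5, s5)
    window = oriented[max(0, t5 - 10) : min(len(oriented), t3 + 10)]
    if span > 0 and window:
        n_frac = window.count("N") / len(window)
        if n_frac >= params.max_n_frac:
            return unresolved("orthologous window is assembly gap (N-run)")

    # element body without the tail; element_seq covers the span including the
    # tail, which precedes the body for minus-strand copies.  The window is in
    # the anchors' shared frame, which mirrors the source forward frame, so
    # the body needs no re-orientation.
    if locus.hit.strand == "+":
        elem = locus.element_seq[: locus.element_len]
    else:
        elem = locus.element_seq[locus.hit.a_tail_len :]
    call = OrthologyCall(
        locus.locus_id, gid, "unresolved", flank5_identity=id5, flank3_identity=id3
    )
    if span > 0 and elem and window:
        aln = smith_waterman(elem, window, params.scoring)
        if aln is not None:
            cov = (aln.q_end - aln.q_start) / max(1, len(elem))
            if cov >= params.present_min_cov and aln.identity >= params.present_min_ident:
                call.state = "present"
                call.gap_len = 0
                return call
    tsd_len = len(locus.hit.tsd.sequence) if locus.hit.tsd else params.tsd_max
    deletion = locus.filled_inner_len - span
    call.gap_len = deletion
    lo = params.gap_low_frac * locus.element_len
    hi = locus.element_len + tsd_len + locus.hit.a_tail_len + params.gap_pad
    if lo <= deletion <= hi:
        call.state = "absent"
        return call
    call.reason = "span matches neither filled nor empty allele"
    return call


@dataclass
class PresenceMatrix:
    """Loci x genomes grid of P/A/U states with derived per-locus labels."""

    states: pd.DataFrame        # index locus_id, columns genome_id, values P/A/U
    labels: pd.Series           # locus_id -> classification label
    calls: list[OrthologyCall] = field(default_factory=list)

    def counts(self) -> pd.Series:
        """Tally of loci per classification bucket (deterministic order)."""
        return self.labels.value_counts().sort_index()


def classify_states(states: Mapping[str, str]) -> str:
    """Label one locus from its per-genome states.

    ``lineage_specific:<g>`` requires presence in exactly one genome and
    absence (not unresolved) everywhere else; any unresolved cell yields
    ``unresolved``.  Present everywhere is ``shared_all``; otherwise
    ``shared:<g1+g2+...>``.
    """
    if any(s == "unresolved" for s in states.values()):
        return "unresolved"
    present = sorted(g for g, s in states.items() if s == "present")
    if len(present) == len(states):
        return "shared_all"
    if len(present) == 1:
        return f"lineage_specific:{present[0]}"
    if len(present) >= 2:
        return "shared:" + "+".join(present)
    return "absent_everywhere"


def build_presence_matrix(
    loci: Sequence[FullLengthElement],
    genomes: Mapping[str, GenomeIndex | list[GenomeRecord]],
    params: OrthologyParams = OrthologyParams(),
) -> PresenceMatrix:
    """Call every locus against every genome and classify.

    The locus's own source genome is scored present by construction (the
    element was detected there).  Loci with unresolved cells are retained and
    labelled ``unresolved``, never dropped.
    """
    indexes: dict[str, GenomeIndex] = {}
    for gid, g in genomes.items():
        indexes[gid] = g if isinstance(g, GenomeIndex) else GenomeIndex(g, params.k)
    rows = {}
    all_calls: list[OrthologyCall] = []
    labels = {}
    for locus in loci:
        states: dict[str, str] = {}
        for gid, idx in indexes.items():
            if gid == locus.hit.genome_id:
                states[gid] = "present"
                all_calls.append(OrthologyCall(locus.locus_id, gid, "present", reason="source"))
                continue
            call = call_orthologous_state(locus, idx, params)
            states[gid] = call.state
            all_calls.append(call)
        rows[locus.locus_id] = {g: s[0].upper() for g, s in states.items()}
        labels[locus.locus_id] = classify_states(states)
    states_df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    states_df = states_df[sorted(states_df.columns)]
    return PresenceMatrix(
        states=states_df,
        labels=pd.Series(labels, name="classification").sort_index(),
        calls=all_calls,
    )


def _best_primer_site(primer: str, seq: str, max_mismatch: int) -> tuple[int, int] | None:
    """(start, mismatches) of the best ungapped primer site, or None."""
    best: tuple[int, int] | None = None
    for i in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(primer, seq[i : i + len(primer)]) if a != b or a == "N")
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (i, mm)
    return best


def amplicon_sizes(
    flank5: str,
    flank3: str,
    primer_pair: tuple[str, str],
    insert_len: int = 0,
    tsd_len: int = 0,
    max_mismatch: int = 2,
) -> tuple[int, int] | None:
    """(empty, filled) PCR product sizes for an insertion between two flanks.

    ``insert_len`` is the inserted block between the flank extraction points
    on the filled allele (element body + A-tail); the empty allele lacks the
    block and one of the two TSD copies.  With no insertion the two sizes are
    equal.  Returns ``None`` when either primer has more than ``max_mismatch``
    mismatches to its flank (no amplification).
    """
    fwd, rev = primer_pair
    site_f = _best_primer_site(fwd, flank5, max_mismatch)
    site_r = _best_primer_site(revcomp(rev), flank3, max_mismatch)
    if site_f is None or site_r is None:
        return None
    filled = (len(flank5) - site_f[0]) + insert_len + (site_r[0] + len(rev))
    empty = filled - (insert_len + tsd_len)
    return empty, filled


def predict_amplicon_sizes(
    locus: FullLengthElement,
    primer_pair: tuple[str, str],
    max_mismatch: int = 2,
) -> tuple[int, int] | None:
    """In-silico PCR product sizes (empty, filled) for a locus.

    The forward primer must sit in the 5' flank (forward orientation) and the
    reverse primer in the 3' flank (reverse-complement orientation), each
    with at most ``max_mismatch`` mismatches; otherwise no amplification is
    predicted and ``None`` is returned.  The filled product exceeds the empty
    product by element length + A-tail + one TSD copy.
    """
    tsd_len = len(locus.hit.tsd.sequence) if locus.hit.tsd else 0
    return amplicon_sizes(
        locus.flank5,
        locus.flank3,
        primer_pair,
        insert_len=locus.filled_inner_len,
        tsd_len=tsd_len,
        max_mismatch=max_mismatch,
    )
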