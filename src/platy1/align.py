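"""Local pairwise alignment core shared by the scanner and orthology anchoring.

A single affine-gap Smith-Waterman (Gotoh) implementation serves both the
full-matrix case (consensus vs. a small candidate window) and the banded case
(flank anchoring around a seeded diagonal).  The gap model is
``cost(L) = gap_open + gap_extend * L`` for a gap of L bases, so a 1-base gap
costs ``gap_open + gap_extend``.

``N`` mismatches everything, including another ``N``: assembly gaps must not
create spurious matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 4
    gap_extend: int = 1


@dataclass
class LocalAlignment:
    """A local alignment; coordinates are 0-based half-open on each sequence."""

    score: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    q_aln: str = field(repr=False, default="")
    r_aln: str = field(repr=False, default="")

    @property
    def aligned_columns(self) -> int:
        """Columns where both sequences contribute a base (no gap)."""
        return sum(1 for a, b in zip(self.q_aln, self.r_aln) if a != "-" and b != "-")

    @property
    def matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.q_aln, self.r_aln)
            if a != "-" and b != "-" and a == b and a != "N"
        )

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.matches / cols if cols else 0.0


_NEG = -(10**9)


def smith_waterman(
    query: str,
    ref: str,
    scoring: Scoring = Scoring(),
    diag: int | None = None,
    band: int | None = None,
) -> LocalAlignment | None:
    """Best-scoring local alignment of ``query`` against ``ref``.

    With ``diag``/``band`` set, only cells with ``(j - i) - diag`` within
    ``[-band, band]`` are computed (banded Gotoh around a seeded diagonal
    ``diag = ref_pos - query_pos``).  Returns ``None`` if no cell scores > 0.

    Tie-break: among equal-scoring end cells the first in row-major order
    wins, which prefers the shortest alignment ending earliest; trailing
    net-zero extensions are trimmed.
    """
    n, m = len(query), len(ref)
    if n == 0 or m == 0:
        return None
    if band is not None and diag is not None and m > n + 2 * band + 2:
        # restrict the reference to the band's footprint so that row storage
        # is O(band + n), not O(len(ref))
        r_lo = max(0, diag - band)
        r_hi = min(m, n + diag + band)
        if r_hi <= r_lo:
            return None
        sub = smith_waterman(query, ref[r_lo:r_hi], scoring, diag=diag - r_lo, band=band)
        if sub is None:
            return None
        sub.r_start += r_lo
        sub.r_end += r_lo
        return sub
    go = scoring.gap_open + scoring.gap_extend  # cost of the first gapped base
    ge = scoring.gap_extend
    ma, mi = scoring.match, scoring.mismatch

    prev_h = [0] * (m + 1)
    prev_f = [_NEG] * (m + 1)
    # pointers: pH[i][j] in {0 stop, 1 diag, 2 from E (gap in query), 3 from F}
    pH: list[bytearray] = [bytearray(m + 1)]
    pE: list[bytearray] = [bytearray(m + 1)]
    pF: list[bytearray] = [bytearray(m + 1)]
    best = 0
    best_ij = (0, 0)

    for i in range(1, n + 1):
        qc = query[i - 1]
        qn = qc == "N"
        row_h = [0] * (m + 1)
        row_f = [_NEG] * (m + 1)
        ph = bytearray(m + 1)
        pe = bytearray(m + 1)
        pf = bytearray(m + 1)
        if band is not None and diag is not None:
            jlo = max(1, i + diag - band)
            jhi = min(m, i + diag + band)
        else:
            jlo, jhi = 1, m
        e = _NEG
        ph_i = prev_h
        pf_i = prev_f
        for j in range(jlo, jhi + 1):
            h_left = row_h[j - 1]
            e_open = h_left - go
            e_ext = e - ge
            if e_open >= e_ext:
                e = e_open
                pe[j] = 1  # opened from H
            else:
                e = e_ext
            f_open = ph_i[j] - go
            f_ext = pf_i[j] - ge
            if f_open >= f_ext:
                f = f_open
                pf[j] = 1
            else:
                f = f_ext
            row_f[j] = f
            rc = ref[j - 1]
            d = ph_i[j - 1] + (ma if (qc == rc and not qn) else mi)
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            row_h[j] = h
            ph[j] = p
            if h > best:
                best = h
                best_ij = (i, j)
        prev_h = row_h
        prev_f = row_f
        pH.append(ph)
        pE.append(pe)
        pF.append(pf)

    if best <= 0:
        return None

    # traceback
    i, j = best_ij
    q_end, r_end = i, j
    qa: list[str] = []
    ra: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = pH[i][j]
            if p == 0:
                break
            if p == 1:
                qa.append(query[i - 1])
                ra.append(ref[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append("-")
            ra.append(ref[j - 1])
            opened = pE[i][j]
            j -= 1
            if opened:
                state = "H"
        else:  # F
            qa.append(query[i - 1])
            ra.append("-")
            opened = pF[i][j]
            i -= 1
            if opened:
                state = "H"
    return LocalAlignment(
        score=best,
        q_start=i,
        q_end=q_end,
        r_start=j,
        r_end=r_end,
        q_aln="".join(reversed(qa)),
        r_aln="".join(reversed(ra)),
    )


class KmerIndex:
    """Exact k-mer index of one sequence (k-mer -> sorted start positions)."""

    def __init__(self, seq: str, k: int = 11):
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            index.setdefault(km, []).append(i)
        self._index = index

    def lookup(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])

    def seeds(self, query: str) -> list[tuple[int, int]]:
        """All (diagonal, ref_pos) exact seed matches of query k-mers."""
        k = self.k
        out: list[tuple[int, int]] = []
        for i in range(len(query) - k + 1):
            km = query[i : i + k]
            if "N" in km:
                continue
            for p in self._index.get(km, ()):
                out.append((p - i, p))
        return out


def cluster_seeds(
    seeds: list[tuple[int, int]], band: int, max_gap: int
) -> list[tuple[int, int, int, int, int]]:
    """Group (diag, pos) seeds into candidate loci.

    Seeds belong to the same cluster when their diagonals differ by at most
    ``band`` and their reference positions by at most ``max_gap``.  Returns
    ``(diag_lo, diag_hi, pos_lo, pos_hi, n_seeds)`` per cluster, sorted by
    position.
    """
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda t: (t[1], t[0]))
    # clusters as mutable summaries: [d_lo, d_hi, p_lo, p_hi, n]
    clusters: list[list[int]] = []
    for d, p in seeds:
        placed = False
        for cl in clusters:
            if cl[0] - band <= d <= cl[1] + band and p - cl[3] <= max_gap:
                cl[0] = min(cl[0], d)
                cl[1] = max(cl[1], d)
                cl[2] = min(cl[2], p)
                cl[3] = max(cl[3], p)
                cl[4] += 1
                placed = True
                break
        if not placed:
            clusters.append([d, d, p, p, 1])
    out = [tuple(cl) for cl in clusters]
    out.sort(key=lambda t: t[2])
    return out
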