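"""Readers and writers for the external representations the pipeline touches.

Internal convention: all genomic intervals are 0-based, half-open.  The only
places 1-based inclusive coordinates appear are at the parse/emit boundaries
of formats that use them (RepeatMasker ``.out``), and in coordinates *on a
consensus sequence* (``cons_begin``/``cons_end`` of a hit), which follow the
1-based inclusive convention of RepeatMasker annotation throughout the
package.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GenomeRecord:
    """One contig of one assembly.

    ``sequence`` is uppercase DNA over {A, C, G, T, N}; ``genome_id`` is a
    short assembly label and ``contig_id`` must be unique within it.
    """

    genome_id: str
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.genome_id}:{self.contig_id}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.genome_id}:{self.contig_id}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatAnnotationRow:
    """One annotation line of a RepeatMasker ``.out`` file.

    Query positions are kept 1-based inclusive exactly as printed.  Consensus
    coordinates are decoded so that ``repeat_begin <= repeat_end`` for both
    strand encodings; ``repeat_left`` is the residual consensus length from
    the parenthesised column.  Strand is normalised to ``+``/``-`` (the file's
    ``C`` maps to ``-``).
    """

    score: int
    perc_div: float
    perc_del: float
    perc_ins: float
    query_contig: str
    query_begin: int
    query_end: int
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_begin: int
    repeat_end: int
    repeat_left: int

    def __post_init__(self) -> None:
        if self.query_begin > self.query_end:
            raise ValueError("query_begin > query_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for v in (self.perc_div, self.perc_del, self.perc_ins):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage out of [0, 100]: {v}")

    @property
    def bed_start(self) -> int:
        return self.query_begin - 1

    @property
    def bed_end(self) -> int:
        return self.query_end


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequence lines are uppercased and stripped of whitespace and gap
    characters (``-``, ``.``).  Residues outside {A, C, G, T, N} raise
    :class:`ParseError` naming the line.  ``genome_id`` defaults to the file's
    base name without extension.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    records: list[GenomeRecord] = []
    header: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: record {header!r} has no sequence (line {line_no})")
        records.append(GenomeRecord(genome_id, header, seq))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {line_no}")
                if header in seen:
                    raise ParseError(f"{path}: duplicate record id {header!r} at line {line_no}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence before any header at line {line_no}")
                seq = line.upper().replace("-", "").replace(".", "").replace(" ", "")
                bad = set(seq) - VALID_BASES
                if bad:
                    raise ParseError(
                        f"{path}: invalid residue(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(seq)
        flush(line_no if records or header else 0)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as wrapped FASTA (one file, record order preserved)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_PAREN = re.compile(r"^\((\d+)\)$")


def _cons_coord(tok: str, line_no: int, path) -> tuple[int, bool]:
    m = _PAREN.match(tok)
    if m:
        return int(m.group(1)), True
    try:
        return int(tok), False
    except ValueError:
        raise ParseError(f"{path}: bad consensus coordinate {tok!r} at line {line_no}") from None


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatAnnotationRow]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard layout is assumed: up to three header lines (column titles
    and a blank line) followed by whitespace-separated annotation rows.  Both
    consensus-coordinate encodings are decoded: ``+`` rows carry
    ``begin end (left)`` and ``C`` rows carry ``(left) end begin``.
    """
    rows: list[RepeatAnnotationRow] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            toks = line.split()
            # header lines start with the literal column titles
            if toks[0] in ("SW", "score", "bit") or toks[0].startswith("-"):
                continue
            if len(toks) < 14:
                raise ParseError(
                    f"{path}: expected >= 14 columns, got {len(toks)} at line {line_no}"
                )
            strand_tok = toks[8]
            if strand_tok not in ("+", "C"):
                raise ParseError(f"{path}: bad strand {strand_tok!r} at line {line_no}")
            c1, p1 = _cons_coord(toks[11], line_no, path)
            c2, _ = _cons_coord(toks[12], line_no, path)
            c3, p3 = _cons_coord(toks[13], line_no, path)
            if strand_tok == "+":
                if p1 or not p3:
                    raise ParseError(f"{path}: + row consensus columns malformed at line {line_no}")
                begin, end, left = c1, c2, c3
            else:
                if p3 or not p1:
                    raise ParseError(f"{path}: C row consensus columns malformed at line {line_no}")
                left, end, begin = c1, c2, c3
            try:
                rows.append(
                    RepeatAnnotationRow(
                        score=int(toks[0]),
                        perc_div=float(toks[1]),
                        perc_del=float(toks[2]),
                        perc_ins=float(toks[3]),
                        query_contig=toks[4],
                        query_begin=int(toks[5]),
                        query_end=int(toks[6]),
                        strand="+" if strand_tok == "+" else "-",
                        repeat_name=toks[9],
                        repeat_class=toks[10],
                        repeat_begin=begin,
                        repeat_end=end,
                        repeat_left=left,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc} at line {line_no}") from None
    return rows


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)  ID\n\n"
)


def write_repeatmasker_out(rows: Sequence[RepeatAnnotationRow], path: str | os.PathLike) -> None:
    """Emit rows in RepeatMasker ``.out`` layout (re-readable by the parser)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, r in enumerate(sorted(rows, key=lambda r: (r.query_contig, r.query_begin)), 1):
            if r.strand == "+":
                cons = f"{r.repeat_begin} {r.repeat_end} ({r.repeat_left})"
            else:
                cons = f"({r.repeat_left}) {r.repeat_end} {r.repeat_begin}"
            strand = "+" if r.strand == "+" else "C"
            fh.write(
                f"{r.score} {r.perc_div:.1f} {r.perc_del:.1f} {r.perc_ins:.1f} "
                f"{r.query_contig} {r.query_begin} {r.query_end} (0) {strand} "
                f"{r.repeat_name} {r.repeat_class} {cons} {i}\n"
            )


def write_bed(hits: Iterable, path: str | os.PathLike) -> None:
    """Write hit-like objects as BED6 (0-based half-open, deterministic order).

    Accepts anything exposing ``genome_id``/``contig_id``/``start``/``end``/
    ``strand`` plus an optional ``subfamily`` and ``score`` (ElementHit), or a
    :class:`RepeatAnnotationRow` (converted via the off-by-one rule).
    """
    lines = []
    for h in hits:
        if isinstance(h, RepeatAnnotationRow):
            lines.append(
                ("", h.query_contig, h.bed_start, h.bed_end, h.repeat_name, h.score, h.strand)
            )
        else:
            lines.append(
                (
                    getattr(h, "genome_id", ""),
                    h.contig_id,
                    h.start,
                    h.end,
                    getattr(h, "subfamily", "."),
                    int(getattr(h, "score", 0)),
                    h.strand,
                )
            )
    lines.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    with open(path, "w") as fh:
        for _, contig, start, end, name, score, strand in lines:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_tsv(table: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Write a DataFrame as tab-separated values with a header row."""
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
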