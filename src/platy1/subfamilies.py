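"""Subfamily discovery from shared diagnostic substitutions.

SINE copies descend from a small number of actively retrotransposing master
(source) elements.  Substitutions the master itself acquires are inherited by
every later copy, so they appear *nonrandomly* across an alignment of copies:
a column where many copies share the same derived base marks a diagnostic
substitution, and the set of copies carrying a co-segregating group of such
columns defines a derived subfamily.

This module formalises the usual manual-alignment inspection as an explicit
statistical rule: a column is a diagnostic candidate when one derived base is
carried by at least ``min_support`` copies and that count is improbable under
independent neutral mutation (binomial tail at per-base rate
``neutral_div / 3``, Bonferroni-corrected across consensus columns).
Candidates are grouped by co-segregation (overlap of their supporting copy
sets) and the best-supported group seeds a derived subfamily; the procedure
recurses into the new subfamily's members and into the remainder, producing a
strictly nested subfamily tree.

Naming follows the field convention: children of a numbered family take
letter suffixes in order (``-4`` -> ``-4a``, ``-4b``); children of a lettered
subfamily append the number of additional diagnostic substitutions
(``-4b`` + 3 new diagnostics -> ``-4b3``); a lineage tag may be appended
(``-4b_aotus``).
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import Scoring, smith_waterman

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def classify_substitution(anc: str, der: str) -> str:
    """``transition`` for purine<->purine or pyrimidine<->pyrimidine, else
    ``transversion``."""
    if anc == der or anc not in "ACGT" or der not in "ACGT":
        raise ValueError(f"invalid substitution {anc}->{der}")
    return "transition" if (anc, der) in TRANSITIONS else "transversion"


@dataclass(frozen=True)
class DiagnosticSubstitution:
    position: int            # 1-based consensus coordinate
    ancestral_base: str
    derived_base: str
    substitution_class: str
    support: int             # copies sharing the derived base
    p_value: float           # binomial enrichment tail probability
    cpg: bool = False        # consensus CpG context (flagged, never excluded)

    def __post_init__(self) -> None:
        if self.ancestral_base == self.derived_base:
            raise ValueError("ancestral and derived base identical")
        if self.substitution_class != classify_substitution(
            self.ancestral_base, self.derived_base
        ):
            raise ValueError("substitution class inconsistent with bases")


@dataclass
class MultipleAlignment:
    """Copies stacked onto consensus columns.

    ``matrix`` is (n_members x n_columns) of single characters; column ``j``
    is consensus position ``j + 1`` (1-based).  Insertions relative to the
    consensus are dropped; positions a copy does not reach are ``-``.
    Columns at or past ``a_tail_start`` are excluded from all downstream
    statistics.
    """

    consensus: str
    member_ids: list[str]
    matrix: np.ndarray
    a_tail_start: int = 0

    def __post_init__(self) -> None:
        if self.a_tail_start == 0:
            self.a_tail_start = len(self.consensus) + 1

    @property
    def n_members(self) -> int:
        return self.matrix.shape[0]

    def body_columns(self) -> range:
        return range(min(len(self.consensus), self.a_tail_start - 1))

    def subset(self, member_idx: Sequence[int]) -> "MultipleAlignment":
        return MultipleAlignment(
            consensus=self.consensus,
            member_ids=[self.member_ids[i] for i in member_idx],
            matrix=self.matrix[list(member_idx)],
            a_tail_start=self.a_tail_start,
        )

    def with_consensus(self, consensus: str) -> "MultipleAlignment":
        return MultipleAlignment(
            consensus=consensus,
            member_ids=self.member_ids,
            matrix=self.matrix,
            a_tail_start=self.a_tail_start,
        )


def align_members_to_consensus(
    members: Iterable[tuple[str, str]],
    consensus: str,
    a_tail_start: int = 0,
    scoring: Scoring = Scoring(),
) -> MultipleAlignment:
    """Project each member's pairwise alignment onto consensus columns.

    ``members`` yields ``(member_id, sequence)``.  Members whose local
    alignment to the consensus has no overlap are excluded with a warning.
    Equal-length members that already sit in consensus coordinates (e.g.
    simulator output) align trivially; diverged genomic copies go through the
    same Smith-Waterman core as the scanner.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    L = len(consensus)
    for mid, seq in members:
        row = np.full(L, "-", dtype="U1")
        aln = smith_waterman(consensus, seq, scoring)
        if aln is None:
            warnings.warn(f"member {mid!r} has no alignment overlap with consensus; excluded")
            continue
        pos = aln.q_start  # 0-based consensus index of next consensus base
        for qc, rc in zip(aln.q_aln, aln.r_aln):
            if qc == "-":
                continue  # insertion relative to consensus: dropped
            if rc != "-":
                row[pos] = rc
            pos += 1
        ids.append(mid)
        rows.append(row)
    if len(rows) < 2:
        raise ValueError("need at least 2 alignable members")
    return MultipleAlignment(
        consensus=consensus,
        member_ids=ids,
        matrix=np.vstack(rows),
        a_tail_start=a_tail_start or len(consensus) + 1,
    )


def stack_aligned(
    members: Iterable[tuple[str, str]], consensus: str, a_tail_start: int = 0
) -> MultipleAlignment:
    """Build an alignment from copies already in consensus coordinates.

    Every member sequence must have the consensus length; use
    :func:`align_members_to_consensus` for genomic copies.
    """
    ids, rows = [], []
    for mid, seq in members:
        if len(seq) != len(consensus):
            raise ValueError(f"member {mid!r} length differs from consensus")
        ids.append(mid)
        rows.append(np.array(list(seq), dtype="U1"))
    return MultipleAlignment(
        consensus=consensus,
        member_ids=ids,
        matrix=np.vstack(rows),
        a_tail_start=a_tail_start or len(consensus) + 1,
    )


@dataclass(frozen=True)
class DiagParams:
    min_frac: float = 0.5     # derived base must account for this fraction of copies
    min_support: int = 5
    alpha: float = 0.05       # Bonferroni-corrected across consensus columns


def estimate_neutral_divergence(aln: MultipleAlignment) -> float:
    """Median per-column mismatch rate, the neutral-noise estimate."""
    rates = []
    for j in aln.body_columns():
        col = aln.matrix[:, j]
        known = col != "-"
        n = int(known.sum())
        if n == 0:
            continue
        rates.append(float((col[known] != aln.consensus[j]).sum()) / n)
    return float(np.median(rates)) if rates else 0.0


def _column_candidates(
    aln: MultipleAlignment, neutral_div: float, min_support: int, alpha: float
) -> list[tuple[DiagnosticSubstitution, np.ndarray]]:
    """Significant (substitution, supporter-mask) pairs, ignoring min_frac.

    A column qualifies when its dominant derived base reaches ``min_support``
    copies and the count is improbable under independent neutral substitution
    at per-base rate ``neutral_div / 3`` (Bonferroni across body columns).
    """
    cols = list(aln.body_columns())
    n_tests = max(1, len(cols))
    p_base = neutral_div / 3.0
    out = []
    cons = aln.consensus
    for j in cols:
        col = aln.matrix[:, j]
        known = col != "-"
        n = int(known.sum())
        if n == 0:
            continue
        best_base, best_k = "", 0
        for b in "ACGT":
            if b == cons[j]:
                continue
            k = int((col == b).sum())
            if k > best_k:
                best_base, best_k = b, k
        if best_k < min_support:
            continue
        pval = float(stats.binom.sf(best_k - 1, n, p_base))
        if pval >= alpha / n_tests:
            continue
        cpg = (j + 1 < len(cons) and cons[j : j + 2] == "CG") or (
            j > 0 and cons[j - 1 : j + 1] == "CG"
        )
        sub = DiagnosticSubstitution(
            position=j + 1,
            ancestral_base=cons[j],
            derived_base=best_base,
            substitution_class=classify_substitution(cons[j], best_base),
            support=best_k,
            p_value=pval,
            cpg=cpg,
        )
        out.append((sub, col == best_base))
    return out


def call_diagnostics(
    aln: MultipleAlignment,
    neutral_div: float | None = None,
    params: DiagParams = DiagParams(),
) -> list[DiagnosticSubstitution]:
    """Diagnostic substitutions relative to the alignment's consensus.

    A column is diagnostic when (a) one derived base accounts for at least
    ``min_frac`` of the copies and at least ``min_support`` copies carry it,
    and (b) the count is binomially improbable under independent neutral
    mutation (see :func:`_column_candidates`).  ``neutral_div`` defaults to
    the median column mismatch rate of the alignment itself.  Fewer copies
    than ``min_support`` yields an empty result with a warning.
    """
    if aln.n_members < params.min_support:
        warnings.warn("fewer copies than min_support; no diagnostics callable")
        return []
    if neutral_div is None:
        neutral_div = estimate_neutral_divergence(aln)
    cands = _column_candidates(aln, neutral_div, params.min_support, params.alpha)
    out = []
    for sub, mask in cands:
        col = aln.matrix[:, sub.position - 1]
        n = int((col != "-").sum())
        if n and sub.support / n >= params.min_frac:
            out.append(sub)
    return sorted(out, key=lambda s: s.position)


@dataclass
class SubfamilyModel:
    """A consensus plus the diagnostic substitutions separating it from its
    parent, with member assignments and child models."""

    name: str
    parent_name: str | None
    consensus: str
    diagnostics: list[DiagnosticSubstitution] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    children: list["SubfamilyModel"] = field(default_factory=list)

    def walk(self) -> Iterable["SubfamilyModel"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def depth(self) -> int:
        return 1 + max((c.depth() for c in self.children), default=0)


def apply_substitutions(consensus: str, subs: Iterable[DiagnosticSubstitution]) -> str:
    seq = list(consensus)
    for s in subs:
        if seq[s.position - 1] != s.ancestral_base:
            raise ValueError(
                f"consensus base at {s.position} is {seq[s.position - 1]}, "
                f"expected {s.ancestral_base}"
            )
        seq[s.position - 1] = s.derived_base
    return "".join(seq)


@dataclass(frozen=True)
class DeriveParams:
    min_support: int = 5
    alpha: float = 0.05
    member_match_frac: float = 0.8
    cluster_jaccard: float = 0.5
    min_frac: float = 0.5
    lineage: str | None = None


_LINEAGE_RE = re.compile(r"_(\w+)$")


def _name_child(parent: SubfamilyModel, n_new: int, lineage: str | None) -> str:
    base = parent.name
    m = _LINEAGE_RE.search(base)
    if m and lineage and m.group(1) == lineage:
        base = base[: m.start()]
    token = base.rsplit("-", 1)[-1]
    if token.isdigit():
        # letter tier: next unused letter among existing children
        taken = set()
        for c in parent.children:
            cb = c.name
            mm = _LINEAGE_RE.search(cb)
            if mm:
                cb = cb[: mm.start()]
            tail = cb[len(base) :]
            if len(tail) == 1 and tail.isalpha():
                taken.add(tail)
        for letter in string.ascii_lowercase:
            if letter not in taken:
                name = base + letter
                break
        else:  # pragma: no cover - >26 children
            name = base + "z" + str(len(parent.children))
    else:
        # additional-mutation tier: append the count of new diagnostics
        name = base + str(n_new)
    if lineage:
        name += f"_{lineage}"
    return name


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.logical_or(a, b).sum())
    return int(np.logical_and(a, b).sum()) / union if union else 0.0


def _best_split(
    aln: MultipleAlignment, params: DeriveParams
) -> tuple[list[DiagnosticSubstitution], np.ndarray] | None:
    """Most-supported co-segregating candidate group and its member mask.

    Candidates are ranked by support; the top candidate seeds a group of all
    candidates whose supporter sets overlap it at Jaccard >=
    ``cluster_jaccard``.  Members are copies matching the derived base at >=
    ``member_match_frac`` of the group's (non-gap) positions.  Seeds are
    tried in decreasing support order until one yields >= ``min_support``
    members.
    """
    neutral = estimate_neutral_divergence(aln)
    cands = _column_candidates(aln, neutral, params.min_support, params.alpha)
    if not cands:
        return None
    cands.sort(key=lambda t: (-t[0].support, t[0].position))
    tried: set[int] = set()
    for seed_sub, seed_mask in cands:
        if seed_sub.position in tried:
            continue
        group = [
            (s, m) for s, m in cands if _jaccard(m, seed_mask) >= params.cluster_jaccard
        ]
        tried.update(s.position for s, _ in group)
        positions = [s.position - 1 for s, _ in group]
        derived = np.array([s.derived_base for s, _ in group], dtype="U1")
        sub_mat = aln.matrix[:, positions]
        known = sub_mat != "-"
        matches = (sub_mat == derived[None, :]) & known
        with np.errstate(invalid="ignore"):
            frac = np.where(
                known.sum(axis=1) > 0, matches.sum(axis=1) / np.maximum(known.sum(axis=1), 1), 0.0
            )
        member_mask = frac >= params.member_match_frac
        if int(member_mask.sum()) >= params.min_support:
            subs = sorted((s for s, _ in group), key=lambda s: s.position)
            return subs, member_mask
    return None


def derive_subfamilies(
    members: MultipleAlignment | Iterable[tuple[str, str]],
    parent: SubfamilyModel,
    params: DeriveParams = DeriveParams(),
) -> SubfamilyModel:
    """Recursively partition copies into nested derived subfamilies.

    ``members`` is either a :class:`MultipleAlignment` against the parent
    consensus or an iterable of ``(id, sequence)`` pairs to be aligned first.
    New children are appended to ``parent`` (existing children, e.g. known
    sibling subfamilies, only influence letter-suffix naming); each child is
    recursed into for grandchildren and the remainder is re-scanned for
    sibling subfamilies.  The result is deterministic for any input order.
    """
    if not isinstance(members, MultipleAlignment):
        members = align_members_to_consensus(members, parent.consensus)
    aln = members.with_consensus(parent.consensus)
    order = np.argsort(np.array(aln.member_ids))
    aln = aln.subset(list(order))
    parent.members = list(aln.member_ids)
    _derive_into(parent, aln, params)
    return parent


def _derive_into(node: SubfamilyModel, aln: MultipleAlignment, params: DeriveParams) -> None:
    remaining = aln
    while remaining.n_members >= params.min_support:
        split = _best_split(remaining, params)
        if split is None:
            break
        subs, mask = split
        child_cons = apply_substitutions(remaining.consensus, subs)
        name = _name_child(node, len(subs), params.lineage)
        member_idx = [i for i, keep in enumerate(mask) if keep]
        child_aln = remaining.subset(member_idx).with_consensus(child_cons)
        child = SubfamilyModel(
            name=name,
            parent_name=node.name,
            consensus=child_cons,
            diagnostics=subs,
            members=list(child_aln.member_ids),
        )
        node.children.append(child)
        _derive_into(child, child_aln, params)
        rest_idx = [i for i, keep in enumerate(mask) if not keep]
        remaining = remaining.subset(rest_idx)
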