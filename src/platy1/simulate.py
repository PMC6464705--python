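"""Synthetic multi-genome datasets with known insertion truth.

The generator emulates the conditions of a small New World monkey
comparative study so that every pipeline stage is testable without genome
downloads:

* a 4-tip species tree (rapid Cebidae-like radiation, root ~21 Myr, with a
  stem lineage above the root so that some insertions are shared by all
  species);
* master-gene SINE amplification: a handful of source elements, each active
  in a bounded time window, some restricted to one lineage (the stealth-like
  pattern of long dormancy followed by lineage-specific daughters);
* target-primed reverse transcription mechanics per insertion: target site
  duplication (5-25 bp), 3' A-rich tail (geometric length), random strand,
  occasional 5' truncation;
* neutral single-rate substitution (0.006024/bp/Myr by default) applied to
  all sequence, inserted copies included, from their moment of insertion -
  equal rates to all alternative bases, no indels, no CpG hypermutability;
* within-species polymorphism: insertions on a terminal branch younger than
  the polymorphic window segregate; their diploid genotypes are drawn from a
  sampled allele frequency.  A configured number of recent insertions on one
  species' branch is reciprocally fixed between two labelled groups of
  individuals, emulating group-diagnostic loci (red- vs gray-necked owl
  monkeys).

Everything is driven by one integer seed: identical configuration and seed
give byte-identical genomes, truth tables and genotype tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .formats import GenomeRecord, write_fasta, write_tsv
from .genotypes import GenotypeTable
from .scanner import ConsensusLibrary

DEFAULT_RATE = 0.006024  # substitutions per base per Myr

# Synthetic 100 bp Platy-1-like root consensus.  This is NOT the RepBase
# Platy-1 consensus (which is not redistributed here); it is a synthetic
# stand-in whose bases at the documented diagnostic positions match the
# ancestral states those diagnostics require, so the reported subfamily substitution
# plans apply verbatim.
ROOT_CONSENSUS_SYNTHETIC = (
    "CTTCTATCTGCGACAAGTGTGCCAGTTGTTGCATCTATTTGAATTAGAGG"
    "GCTAGCAAGATAAGAGGACCTGCATGCGCTGACTACTACCCAGAGTTGCA"
)

# Diagnostic substitution plans, (1-based position, derived base).
# The 4b/4b3 plans are the reported owl-monkey subfamily diagnostics; the Platy-1-4
# and 4a plans are synthetic, at positions disjoint from them.
PLAN_P4 = ((15, "G"), (38, "C"), (47, "A"), (73, "T"), (88, "G"))
PLAN_P4A = ((8, "T"), (33, "C"), (55, "A"), (91, "T"))
PLAN_4B = ((19, "C"), (26, "A"), (64, "T"), (70, "G"), (79, "T"), (82, "G"))
PLAN_4B3 = ((12, "A"), (62, "G"), (100, "G"))

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(list("ACGT"), dtype="U1")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def evolve_master(parent: str, plan: Iterable[tuple[int, str]]) -> str:
    """Apply a diagnostic plan (1-based position -> derived base) to a parent
    master sequence; an empty plan returns the parent unchanged."""
    seq = list(parent)
    for pos, base in plan:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"plan position {pos} outside consensus")
        if base not in "ACGT":
            raise ValueError(f"bad derived base {base!r}")
        seq[pos - 1] = base
    return "".join(seq)


def expected_divergence(insertion_time: float, rate: float = DEFAULT_RATE) -> float:
    """Expected substituted-base proportion after ``insertion_time`` Myr
    (linear single-rate clock, the inverse of the T = D/t age estimate)."""
    if insertion_time < 0 or rate < 0:
        raise ValueError("time and rate must be non-negative")
    return insertion_time * rate


@dataclass(frozen=True)
class MasterSpec:
    """One master (source) element: its activity window and diagnostic plan.

    ``start``/``end`` are Myr before present (start > end); ``rate`` is
    insertion events per branch per Myr while active; ``lineages`` restricts
    activity to branches whose descendant tips all belong to the named
    species (``None`` = any branch).  ``diagnostics`` are relative to the
    parent master.
    """

    name: str
    parent: str | None
    diagnostics: tuple[tuple[int, str], ...]
    start: float
    end: float
    rate: float
    lineages: tuple[str, ...] | None = None


def default_masters() -> list[MasterSpec]:
    """The default master schedule: two old broadly active subfamilies, one
    intermediate, and two recent owl-monkey-restricted daughters."""
    return [
        MasterSpec("Platy-1-2", None, (), 31.0, 14.0, 0.30),
        MasterSpec("Platy-1-4", "Platy-1-2", PLAN_P4, 22.0, 6.0, 0.25),
        MasterSpec("Platy-1-4a", "Platy-1-4", PLAN_P4A, 20.0, 5.0, 0.25),
        MasterSpec("Platy-1-4b_aotus", "Platy-1-4", PLAN_4B, 6.0, 0.0, 1.5, ("owl",)),
        MasterSpec("Platy-1-4b3_aotus", "Platy-1-4b_aotus", PLAN_4B3, 2.5, 0.0, 1.2, ("owl",)),
    ]


def build_master_library(masters: Sequence[MasterSpec], root: str = ROOT_CONSENSUS_SYNTHETIC
                         ) -> ConsensusLibrary:
    """Resolve cumulative diagnostic plans into a consensus library."""
    seqs: dict[str, str] = {}
    pending = list(masters)
    while pending:
        progressed = False
        for m in list(pending):
            if m.parent is None:
                seqs[m.name] = evolve_master(root, m.diagnostics)
            elif m.parent in seqs:
                seqs[m.name] = evolve_master(seqs[m.parent], m.diagnostics)
            else:
                continue
            pending.remove(m)
            progressed = True
        if not progressed:
            raise ValueError("master parent references do not resolve")
    return ConsensusLibrary({m.name: seqs[m.name] for m in masters})


DEFAULT_TREE = "(((squirrel:15.0,capuchin:15.0):4.5,owl:19.5):1.5,marmoset:21.0);"


@dataclass
class SimulationConfig:
    seed: int = 42
    tree: str = DEFAULT_TREE
    stem_myr: float = 10.0            # lineage above the root; its insertions are shared by all
    ancestor_length: int = 120_000
    substitution_rate: float = DEFAULT_RATE
    masters: list[MasterSpec] = field(default_factory=default_masters)
    root_consensus: str = ROOT_CONSENSUS_SYNTHETIC
    tsd_len_range: tuple[int, int] = (5, 25)
    a_tail_mean: float = 15.0
    truncation_prob: float = 0.1
    truncation_range: tuple[int, int] = (5, 40)
    polymorphic_window: float = 2.0   # Myr; terminal insertions younger than this segregate
    n_individuals: dict = field(
        default_factory=lambda: {"owl": 23, "squirrel": 32, "capuchin": 14, "marmoset": 10}
    )
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    group_species: str = "owl"
    groups: tuple[str, str] = ("red", "gray")
    n_group_one: int = 12             # first group size within group_species panel
    n_group_diagnostic: int = 3       # forced reciprocally fixed recent insertions
    group_split_time: float = 1.0     # Myr; the two groups' divergence


@dataclass
class _Annot:
    locus_id: str
    block_start: int  # 0-based start of TSD-excluded inserted block (element body + tail)
    block_len: int
    elem_start: int   # consensus-aligned body within the block
    elem_end: int
    strand: str


@dataclass
class SimulatedDataset:
    genomes: dict[str, GenomeRecord]
    truth: pd.DataFrame
    positions: pd.DataFrame
    genotype_tables: dict[str, GenotypeTable]
    library: ConsensusLibrary
    config: SimulationConfig

    def save(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sp, rec in self.genomes.items():
            write_fasta([rec], os.path.join(outdir, f"{sp}.fa"))
        write_tsv(self.truth, os.path.join(outdir, "truth.tsv"))
        write_tsv(self.positions, os.path.join(outdir, "positions.tsv"))
        lib_recs = [
            GenomeRecord("library", name, seq) for name, seq in self.library.entries.items()
        ]
        write_fasta(lib_recs, os.path.join(outdir, "library.fa"))
        for sp, table in self.genotype_tables.items():
            table.write(
                os.path.join(outdir, f"genotypes_{sp}.tsv"),
                os.path.join(outdir, f"meta_{sp}.tsv"),
            )


def _mutate(arr: np.ndarray, dt: float, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Neutral substitution over ``dt`` Myr (Jukes-Cantor per-site kernel)."""
    if dt <= 0 or len(arr) == 0:
        return arr
    p = 0.75 * (1.0 - np.exp(-4.0 * mu * dt / 3.0))
    mask = rng.random(len(arr)) < p
    n = int(mask.sum())
    if n:
        arr = arr.copy()
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return arr


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.library = build_master_library(config.masters, config.root_consensus)
        self.codes = {m.name: _encode(self.library.entries[m.name]) for m in config.masters}
        self.counter = 0
        self.truth_rows: list[dict] = []
        self.positions: list[dict] = []
        self.tip_annots: dict[str, list[_Annot]] = {}

        tree = dendropy.Tree.get(data=config.tree, schema="newick")
        tree.calc_node_ages(ultrametricity_precision=1.0)
        self.tree = tree
        self.root_age = tree.seed_node.age

    # -- event machinery -------------------------------------------------

    def _branch_events(self, age_hi: float, age_lo: float, tips: frozenset[str]
                       ) -> list[tuple[float, MasterSpec, bool]]:
        events: list[tuple[float, MasterSpec, bool]] = []
        for m in self.cfg.masters:
            if m.lineages is not None and not tips <= set(m.lineages):
                continue
            lo = max(age_lo, m.end)
            hi = min(age_hi, m.start)
            if hi <= lo:
                continue
            n = self.rng.poisson(m.rate * (hi - lo))
            for t in self.rng.uniform(lo, hi, size=n):
                events.append((float(t), m, False))
        # forced group-diagnostic insertions on the group species' terminal branch
        if tips == frozenset((self.cfg.group_species,)) and age_lo <= self.cfg.group_split_time <= age_hi:
            active = [
                m
                for m in self.cfg.masters
                if m.end <= self.cfg.group_split_time <= m.start
                and (m.lineages is None or tips <= set(m.lineages))
            ]
            for _ in range(self.cfg.n_group_diagnostic):
                m = active[int(self.rng.integers(len(active)))] if active else self.cfg.masters[-1]
                events.append((self.cfg.group_split_time, m, True))
        events.sort(key=lambda e: -e[0])  # oldest first
        return events

    def _insert(
        self,
        seq: np.ndarray,
        annots: list[_Annot],
        master: MasterSpec,
        time: float,
        branch_label: str,
        group_diag: bool,
    ) -> np.ndarray:
        rng = self.rng
        cfg = self.cfg
        body = self.codes[master.name]
        trunc = 0
        if rng.random() < cfg.truncation_prob:
            trunc = int(rng.integers(cfg.truncation_range[0], cfg.truncation_range[1] + 1))
            body = body[trunc:]
        tail_len = int(rng.geometric(1.0 / cfg.a_tail_mean))
        tail = np.zeros(tail_len, dtype=np.uint8)  # code 0 == A
        strand = "+" if rng.random() < 0.5 else "-"
        block = np.concatenate([body, tail])
        if strand == "-":
            block = _revcomp_codes(block)
        tsd_len = int(rng.integers(cfg.tsd_len_range[0], cfg.tsd_len_range[1] + 1))
        pos = -1
        for _ in range(1000):
            cand = int(rng.integers(0, len(seq) - tsd_len))
            if all(
                cand + tsd_len <= a.block_start or cand >= a.block_start + a.block_len
                for a in annots
            ):
                pos = cand
                break
        if pos < 0:
            raise RuntimeError("could not place insertion outside existing elements")
        tsd = seq[pos : pos + tsd_len]
        new_seq = np.concatenate([seq[: pos + tsd_len], block, seq[pos:]])
        shift = tsd_len + len(block)
        for a in annots:
            if a.block_start >= pos:
                a.block_start += shift
                a.elem_start += shift
                a.elem_end += shift
        self.counter += 1
        locus_id = f"L{self.counter:04d}"
        bs = pos + tsd_len
        if strand == "+":
            es, ee = bs, bs + len(body)
        else:
            es, ee = bs + tail_len, bs + tail_len + len(body)
        annots.append(
            _Annot(locus_id, bs, len(block), es, ee, strand)
        )
        self.truth_rows.append(
            dict(
                locus_id=locus_id,
                master=master.name,
                branch=branch_label,
                time_myr=round(time, 4),
                strand=strand,
                tsd_len=tsd_len,
                tsd_seq=_decode(tsd),
                a_tail_len=tail_len,
                truncation=trunc,
                group_diagnostic=group_diag,
            )
        )
        return new_seq

    # -- tree traversal ---------------------------------------------------

    def run(self) -> SimulatedDataset:
        cfg = self.cfg
        mu = cfg.substitution_rate
        ancestor = self.rng.integers(0, 4, size=cfg.ancestor_length).astype(np.uint8)
        all_tips = frozenset(l.taxon.label for l in self.tree.leaf_node_iter())

        def evolve_branch(seq, annots, age_hi, age_lo, tips, label):
            t_cur = age_hi
            for t_ev, master, forced in self._branch_events(age_hi, age_lo, tips):
                seq = _mutate(seq, t_cur - t_ev, mu, self.rng)
                seq = self._insert(seq, annots, master, t_ev, label, forced)
                t_cur = t_ev
            return _mutate(seq, t_cur - age_lo, mu, self.rng)

        # stem above the root: everything here is shared by all species
        annots: list[_Annot] = []
        seq = evolve_branch(
            ancestor, annots, self.root_age + cfg.stem_myr, self.root_age, all_tips, "stem"
        )

        def recurse(node, seq, annots):
            for child in node.child_nodes():
                c_seq = seq.copy()
                c_annots = [replace(a) for a in annots]
                if child.is_leaf():
                    label = child.taxon.label
                    tips = frozenset((label,))
                else:
                    tips = frozenset(l.taxon.label for l in child.leaf_iter())
                    label = "+".join(sorted(tips))
                c_seq = evolve_branch(c_seq, c_annots, node.age, child.age, tips, label)
                if child.is_leaf():
                    self.tip_annots[child.taxon.label] = c_annots
                    self.tip_seqs[child.taxon.label] = c_seq
                else:
                    recurse(child, c_seq, c_annots)

        self.tip_seqs: dict[str, np.ndarray] = {}
        recurse(self.tree.seed_node, seq, annots)

        genomes = {
            sp: GenomeRecord(sp, "chr1", _decode(arr)) for sp, arr in self.tip_seqs.items()
        }
        for sp, anns in self.tip_annots.items():
            for a in anns:
                self.positions.append(
                    dict(
                        locus_id=a.locus_id,
                        species=sp,
                        block_start=a.block_start,
                        block_end=a.block_start + a.block_len,
                        elem_start=a.elem_start,
                        elem_end=a.elem_end,
                        strand=a.strand,
                    )
                )
        truth_cols = [
            "locus_id", "master", "branch", "time_myr", "strand", "tsd_len", "tsd_seq",
            "a_tail_len", "truncation", "group_diagnostic",
        ]
        truth = pd.DataFrame(self.truth_rows, columns=truth_cols)
        present = {
            lid: sorted(
                sp for sp, anns in self.tip_annots.items() if any(a.locus_id == lid for a in anns)
            )
            for lid in truth["locus_id"]
        }
        truth["present_in"] = truth["locus_id"].map(lambda l: "+".join(present[l]))
        truth["n_species"] = truth["locus_id"].map(lambda l: len(present[l]))
        genotype_tables = self._sample_genotypes(truth)
        truth = truth.merge(self._panel_labels, on="locus_id", how="left")
        pos_cols = [
            "locus_id", "species", "block_start", "block_end", "elem_start", "elem_end", "strand",
        ]
        positions = pd.DataFrame(self.positions, columns=pos_cols).sort_values(
            ["species", "block_start"], kind="stable"
        )
        return SimulatedDataset(
            genomes=genomes,
            truth=truth,
            positions=positions.reset_index(drop=True),
            genotype_tables=genotype_tables,
            library=self.library,
            config=cfg,
        )

    # -- genotypes --------------------------------------------------------

    def _sample_genotypes(self, truth: pd.DataFrame) -> dict[str, GenotypeTable]:
        cfg = self.cfg
        tables: dict[str, GenotypeTable] = {}
        label_rows = []
        for sp, n_ind in sorted(cfg.n_individuals.items()):
            if sp not in self.tip_annots:
                continue
            individuals = [f"{sp}_{i + 1:02d}" for i in range(n_ind)]
            meta = pd.DataFrame(index=pd.Index(individuals, name="individual"))
            meta["species"] = sp
            if sp == cfg.group_species:
                meta["group"] = [
                    cfg.groups[0] if i < cfg.n_group_one else cfg.groups[1]
                    for i in range(n_ind)
                ]
            panel = truth[truth["branch"] == sp]
            data = {}
            for _, row in panel.iterrows():
                lid = row["locus_id"]
                if row["group_diagnostic"]:
                    gts = [
                        "11" if meta.loc[ind, "group"] == cfg.groups[0] else "00"
                        for ind in individuals
                    ]
                    freq = np.nan
                elif row["time_myr"] <= cfg.polymorphic_window:
                    freq = float(self.rng.uniform(*cfg.allele_freq_range))
                    gts = []
                    for _ind in individuals:
                        alleles = int(self.rng.random() < freq) + int(self.rng.random() < freq)
                        gts.append({0: "00", 1: "10", 2: "11"}[alleles])
                else:
                    freq = 1.0
                    gts = ["11"] * n_ind
                data[lid] = gts
                called = pd.Series(gts)
                if (called == "11").all():
                    lab = "fixed_present"
                elif (called == "00").all():
                    lab = "fixed_absent"
                else:
                    lab = "polymorphic"
                label_rows.append(dict(locus_id=lid, allele_freq=freq, panel_label=lab))
            df = pd.DataFrame.from_dict(data, orient="index", columns=individuals)
            df.index.name = "locus_id"
            tables[sp] = GenotypeTable(data=df, meta=meta)
        self._panel_labels = pd.DataFrame(
            label_rows, columns=["locus_id", "allele_freq", "panel_label"]
        )
        return tables


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None
                     ) -> SimulatedDataset:
    """Run the generator; ``seed`` overrides ``config.seed`` when given."""
    cfg = config if config is not None else SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return _Simulator(cfg).run()


def simulate_copy_set(
    consensus: str,
    n: int,
    noise: float,
    rng: np.random.Generator | int,
    prefix: str = "copy",
) -> list[tuple[str, str]]:
    """``n`` copies of ``consensus`` with iid per-site noise.

    Each site independently substitutes to a uniform alternative base with
    probability ``noise``; copies stay in consensus coordinates (no indels),
    so they can be stacked directly with
    :func:`platy1.subfamilies.stack_aligned`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = _encode(consensus)
    out = []
    for i in range(n):
        arr = base.copy()
        mask = rng.random(len(arr)) < noise
        k = int(mask.sum())
        if k:
            arr[mask] = (arr[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
        out.append((f"{prefix}_{i + 1:03d}", _decode(arr)))
    return out
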