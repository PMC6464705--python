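"""Flank-anchored presence/absence calling on constructed and simulated loci."""

import numpy as np
import pytest

from platy1.catalog import FullLengthElement
from platy1.formats import GenomeRecord
from platy1.orthology import (
    GenomeIndex,
    amplicon_sizes,
    build_presence_matrix,
    call_orthologous_state,
    classify_states,
    predict_amplicon_sizes,
)
from platy1.scanner import ElementHit, TSDAnnotation

RNG = np.random.default_rng(31)
BASES = np.array(list("ACGT"))


def rand_dna(n, rng=RNG):
    return "".join(rng.choice(BASES, n))


def build_pair(rng, elem_len=100, tail_len=15, tsd_len=12, flank=600):
    """A filled genome, its empty-allele counterpart, and the locus object."""
    left = rand_dna(800, rng)
    right = rand_dna(800, rng)
    tsd = rand_dna(tsd_len, rng)
    elem = rand_dna(elem_len, rng)
    filled_seq = left + tsd + elem + "A" * tail_len + tsd + right
    empty_seq = left + tsd + right
    es = len(left) + tsd_len          # element body start in filled genome
    ee = es + elem_len                # body end; tail follows
    hit = ElementHit(
        genome_id="filled", contig_id="c", start=es, end=ee, strand="+",
        subfamily="P", cons_begin=1, cons_end=elem_len, perc_div=0.0, score=elem_len,
        tsd=TSDAnnotation((es - tsd_len, es), (ee + tail_len, ee + tail_len + tsd_len), tsd),
        a_tail_len=tail_len,
    )
    span_start, span_end = es, ee + tail_len
    locus = FullLengthElement(
        hit=hit,
        flank5=filled_seq[span_start - flank : span_start],
        flank3=filled_seq[span_end : span_end + flank],
        locus_id="locus1",
        element_seq=filled_seq[span_start:span_end],
    )
    return filled_seq, empty_seq, locus


def test_absent_call_with_expected_gap():
    """The empty-allele genome yields 'absent' with a deletion near
    element + tail + TSD (the ~100 bp gap signature)."""
    rng = np.random.default_rng(1)
    filled, empty, locus = build_pair(rng)
    call = call_orthologous_state(locus, [GenomeRecord("empty", "c", empty)])
    assert call.state == "absent"
    assert call.gap_len == pytest.approx(100 + 15 + 12, abs=6)


def test_present_call_in_identical_genome():
    rng = np.random.default_rng(2)
    filled, empty, locus = build_pair(rng)
    call = call_orthologous_state(locus, [GenomeRecord("same", "c", filled)])
    assert call.state == "present"


def test_present_call_survives_divergence():
    rng = np.random.default_rng(3)
    filled, empty, locus = build_pair(rng)
    # ~8% substitution everywhere, as between sister species
    arr = list(filled)
    for i in range(len(arr)):
        if rng.random() < 0.08:
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
    call = call_orthologous_state(locus, [GenomeRecord("sister", "c", "".join(arr))])
    assert call.state == "present"


def test_n_run_window_is_unresolved():
    rng = np.random.default_rng(4)
    filled, empty, locus = build_pair(rng)
    es, ee = locus.hit.start, locus.hit.end + locus.hit.a_tail_len
    masked = filled[:es] + "N" * (ee - es) + filled[ee:]
    call = call_orthologous_state(locus, [GenomeRecord("gap", "c", masked)])
    assert call.state == "unresolved"
    assert "N-run" in call.reason or "gap" in call.reason


def test_missing_orthologous_region_is_unresolved():
    rng = np.random.default_rng(5)
    filled, empty, locus = build_pair(rng)
    call = call_orthologous_state(locus, [GenomeRecord("other", "c", rand_dna(3000, rng))])
    assert call.state == "unresolved"


def test_short_flank_is_unresolved():
    rng = np.random.default_rng(6)
    filled, empty, locus = build_pair(rng)
    locus.flank5 = locus.flank5[-50:]
    call = call_orthologous_state(locus, [GenomeRecord("empty", "c", empty)])
    assert call.state == "unresolved"
    assert "min_anchor" in call.reason


def test_classify_states_buckets():
    gs = ["a", "b", "c", "d"]
    mk = lambda pres: {g: ("present" if g in pres else "absent") for g in gs}
    assert classify_states(mk(gs)) == "shared_all"
    assert classify_states(mk(["a"])) == "lineage_specific:a"
    assert classify_states(mk(["b", "c"])) == "shared:b+c"
    states = mk(["a"])
    states["d"] = "unresolved"
    assert classify_states(states) == "unresolved"


def test_identical_genomes_have_no_lineage_specific_loci():
    """Byte-identical genomes cannot disagree on any locus."""
    rng = np.random.default_rng(7)
    filled, _, locus = build_pair(rng)
    genomes = {
        "filled": GenomeIndex([GenomeRecord("filled", "c", filled)]),
        "twin": GenomeIndex([GenomeRecord("twin", "c", filled)]),
    }
    pm = build_presence_matrix([locus], genomes)
    assert list(pm.labels) == ["shared_all"]


def test_every_locus_in_exactly_one_bucket(dataset, pipeline, genome_indexes):
    """Conservation: the classification buckets partition the loci."""
    loci = [l for ll in pipeline["loci"].values() for l in ll]
    pm = build_presence_matrix(loci, genome_indexes)
    assert sorted(pm.labels.index) == sorted(l.locus_id for l in loci)
    assert pm.counts().sum() == len(loci)
    assert set(pm.states.columns) == set(dataset.genomes)


def test_presence_matrix_matches_simulation_truth(dataset, pipeline, genome_indexes):
    """Fully anchored loci are classified with near-perfect accuracy."""
    from conftest import match_truth_locus

    loci = [l for ll in pipeline["loci"].values() for l in ll]
    pm = build_presence_matrix(loci, genome_indexes)
    truth = dataset.truth.set_index("locus_id")
    species = sorted(dataset.genomes)

    def truth_label(lid):
        present = sorted(truth.loc[lid, "present_in"].split("+"))
        if len(present) == len(species):
            return "shared_all"
        if len(present) == 1:
            return f"lineage_specific:{present[0]}"
        return "shared:" + "+".join(present)

    n_ok = n_tot = 0
    for locus in loci:
        row = match_truth_locus(dataset, locus.hit)
        if row is None:
            continue
        pred = pm.labels[locus.locus_id]
        if pred == "unresolved":
            continue
        n_tot += 1
        n_ok += pred == truth_label(row.locus_id)
    assert n_tot >= 40
    assert n_ok / n_tot >= 0.95


def test_amplicon_size_arithmetic():
    """Filled - empty = element + A-tail + one TSD copy."""
    rng = np.random.default_rng(9)
    flank5, flank3 = rand_dna(300, rng), rand_dna(300, rng)
    fwd = flank5[210:230]
    rev_site = flank3[80:100]
    from platy1.formats import revcomp

    rev = revcomp(rev_site)
    sizes = amplicon_sizes(flank5, flank3, (fwd, rev), insert_len=115, tsd_len=12)
    empty, filled = sizes
    # the empty allele keeps a single TSD copy, shared by both flanks
    assert empty == (300 - 210) + (80 + 20) - 12
    assert filled - empty == 115 + 12


def test_amplicon_no_insertion_sizes_equal():
    rng = np.random.default_rng(10)
    flank5, flank3 = rand_dna(300, rng), rand_dna(300, rng)
    from platy1.formats import revcomp

    pair = (flank5[250:270], revcomp(flank3[40:60]))
    empty, filled = amplicon_sizes(flank5, flank3, pair)
    assert empty == filled


def test_amplicon_three_mismatches_fail():
    rng = np.random.default_rng(12)
    filled, _, locus = build_pair(rng)
    fwd = locus.flank5[400:422]
    from platy1.formats import revcomp

    rev = revcomp(locus.flank3[100:122])
    assert predict_amplicon_sizes(locus, (fwd, rev)) is not None
    bad = "".join(
        {"A": "C", "C": "G", "G": "T", "T": "A"}[c] if i in (2, 8, 15) else c
        for i, c in enumerate(fwd)
    )
    assert predict_amplicon_sizes(locus, (bad, rev)) is None


def test_simulated_locus_amplicon(dataset, pipeline):
    """Band-size difference equals the planted block length + one TSD."""
    from conftest import match_truth_locus

    truth = dataset.truth.set_index("locus_id")
    done = 0
    for sp, loci in pipeline["loci"].items():
        for locus in loci:
            row = match_truth_locus(dataset, locus.hit)
            if row is None or len(locus.flank5) < 300 or len(locus.flank3) < 300:
                continue
            t = truth.loc[row.locus_id]
            if locus.hit.tsd is None or t.truncation:
                continue
            fwd = locus.flank5[350:372]
            from platy1.formats import revcomp

            rev = revcomp(locus.flank3[150:172])
            sizes = predict_amplicon_sizes(locus, (fwd, rev))
            assert sizes is not None
            empty, filled = sizes
            assert filled - empty == locus.filled_inner_len + len(locus.hit.tsd.sequence)
            done += 1
            break
        if done:
            break
    assert done == 1
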