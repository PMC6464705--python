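"""Diagnostic-substitution calling and nested subfamily derivation."""

import numpy as np
import pytest

from platy1.simulate import (
    PLAN_4B,
    PLAN_4B3,
    PLAN_P4,
    ROOT_CONSENSUS_SYNTHETIC,
    evolve_master,
    simulate_copy_set,
)
from platy1.subfamilies import (
    DeriveParams,
    DiagParams,
    SubfamilyModel,
    align_members_to_consensus,
    call_diagnostics,
    classify_substitution,
    derive_subfamilies,
    stack_aligned,
)

P4 = evolve_master(ROOT_CONSENSUS_SYNTHETIC, PLAN_P4)
P4B = evolve_master(P4, PLAN_4B)
P4B3 = evolve_master(P4B, PLAN_4B3)


@pytest.mark.parametrize(
    "anc,der,expected",
    [(a, d, "transition" if {a, d} in ({"A", "G"}, {"C", "T"}) else "transversion")
     for a in "ACGT" for d in "ACGT" if a != d],
)
def test_classify_substitution_all_12_pairs(anc, der, expected):
    assert classify_substitution(anc, der) == expected


def test_classify_substitution_counts():
    pairs = [(a, d) for a in "ACGT" for d in "ACGT" if a != d]
    classes = [classify_substitution(a, d) for a, d in pairs]
    assert classes.count("transition") == 4
    assert classes.count("transversion") == 8


def test_classify_substitution_rejects_identity():
    with pytest.raises(ValueError):
        classify_substitution("A", "A")


def test_align_members_exact_copies_no_variants():
    aln = stack_aligned([("a", P4), ("b", P4)], P4)
    assert call_diagnostics(aln, params=DiagParams(min_support=1)) == []


def test_align_members_projects_single_substitution():
    copy = list(P4)
    copy[18] = "C"  # consensus position 19
    aln = align_members_to_consensus([("a", "".join(copy)), ("b", P4)], P4)
    variant_cols = [
        j + 1
        for j in range(len(P4))
        if set(aln.matrix[:, j]) - {"-"} != {P4[j]}
    ]
    assert variant_cols == [19]


def test_align_members_drops_insertions_relative_to_consensus():
    copy = P4[:50] + "ACGTACGT" + P4[50:]
    aln = align_members_to_consensus([("a", copy), ("b", P4)], P4)
    assert aln.matrix.shape == (2, len(P4))
    assert "".join(aln.matrix[0]) == P4


def test_align_members_excludes_unalignable_with_warning():
    with pytest.warns(UserWarning, match="excluded"):
        aln = align_members_to_consensus(
            [("a", P4), ("b", P4), ("junk", "N" * 60)], P4
        )
    assert aln.member_ids == ["a", "b"]


def test_planted_diagnostics_recovered_exactly():
    """58 of 68 copies carrying the six derived bases yield exactly those six
    positions."""
    rng = np.random.default_rng(23)
    copies = simulate_copy_set(P4B, 58, 0.01, rng, "sub") + simulate_copy_set(
        P4, 10, 0.01, rng, "anc"
    )
    aln = stack_aligned(copies, P4)
    subs = call_diagnostics(aln)
    assert [s.position for s in subs] == [19, 26, 64, 70, 79, 82]
    by_pos = {s.position: s for s in subs}
    assert by_pos[19].substitution_class == "transversion"
    assert by_pos[79].substitution_class == "transition"
    assert all(s.support >= 50 for s in subs)


def test_call_diagnostics_too_few_copies():
    copies = simulate_copy_set(P4B, 3, 0.01, 5, "c")
    aln = stack_aligned(copies, P4)
    with pytest.warns(UserWarning):
        assert call_diagnostics(aln) == []


def test_null_type_one_error_control():
    """Unstructured noise rarely produces any diagnostic call."""
    nonempty = 0
    for rep in range(40):
        copies = simulate_copy_set(ROOT_CONSENSUS_SYNTHETIC, 100, 0.02, 5000 + rep, "n")
        aln = stack_aligned(copies, ROOT_CONSENSUS_SYNTHETIC)
        nonempty += bool(call_diagnostics(aln))
    assert nonempty <= 2


def test_min_frac_monotonicity():
    """Raising min_frac never increases the number of diagnostic positions."""
    rng = np.random.default_rng(41)
    copies = simulate_copy_set(P4B, 40, 0.015, rng, "s") + simulate_copy_set(
        P4, 28, 0.015, rng, "a"
    )
    aln = stack_aligned(copies, P4)
    sizes = [
        len(call_diagnostics(aln, params=DiagParams(min_frac=f)))
        for f in (0.1, 0.3, 0.5, 0.7, 0.9)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_nested_two_tier_recovery_and_naming():
    """A planted parent/child/grandchild family is recovered at depth 3 with
    field-convention names."""
    rng = np.random.default_rng(7)
    copies = simulate_copy_set(P4B, 58, 0.01, rng, "c4b") + simulate_copy_set(
        P4B3, 10, 0.01, rng, "c4b3"
    )
    parent = SubfamilyModel("Platy-1-4", None, P4)
    parent.children.append(
        SubfamilyModel("Platy-1-4a", "Platy-1-4", evolve_master(P4, ((8, "T"),)))
    )
    tree = derive_subfamilies(
        stack_aligned(copies, P4), parent, DeriveParams(lineage="aotus")
    )
    names = [n.name for n in tree.walk()]
    assert names == ["Platy-1-4", "Platy-1-4a", "Platy-1-4b_aotus", "Platy-1-4b3_aotus"]
    child = tree.children[1]
    assert [d.position for d in child.diagnostics] == [19, 26, 64, 70, 79, 82]
    assert child.consensus == P4B
    grandchild = child.children[0]
    assert [d.position for d in grandchild.diagnostics] == [12, 62, 100]
    assert max(d.position for d in grandchild.diagnostics) == 100
    assert grandchild.consensus == P4B3
    assert len(grandchild.members) >= 8
    assert tree.depth() == 3


def test_homogeneous_set_single_node():
    copies = simulate_copy_set(P4, 30, 0.01, 3, "h")
    parent = SubfamilyModel("Platy-1-4", None, P4)
    tree = derive_subfamilies(stack_aligned(copies, P4), parent)
    assert tree.children == []
    assert len(tree.members) == 30


def test_recovered_child_yields_no_further_splits():
    """Consistency: re-deriving on a recovered child's members is stable."""
    rng = np.random.default_rng(13)
    copies = simulate_copy_set(P4B, 40, 0.01, rng, "c")
    parent = SubfamilyModel("Platy-1-4", None, P4)
    tree = derive_subfamilies(stack_aligned(copies, P4), parent)
    child = tree.children[0]
    redo = derive_subfamilies(
        stack_aligned([c for c in copies if c[0] in child.members], child.consensus),
        SubfamilyModel(child.name, None, child.consensus),
    )
    assert redo.children == []


def test_name_determinism_under_input_order():
    rng = np.random.default_rng(29)
    copies = simulate_copy_set(P4B, 30, 0.01, rng, "x") + simulate_copy_set(
        P4, 30, 0.01, rng, "y"
    )
    def run(cs):
        parent = SubfamilyModel("Platy-1-4", None, P4)
        tree = derive_subfamilies(stack_aligned(cs, P4), parent)
        return [(n.name, tuple(sorted(n.members))) for n in tree.walk()]
    assert run(copies) == run(copies[::-1])


def test_parameter_recovery_across_seeds():
    """Position-level recall and precision >= 0.95 over 20 seeded runs
    (parent n=60, child fraction 0.5, 6 diagnostics, 1-2% noise)."""
    planted = set(p for p, _ in PLAN_4B)
    tp = fp = fn = 0
    for rep in range(20):
        rng = np.random.default_rng(900 + rep)
        noise = 0.01 if rep % 2 == 0 else 0.02
        copies = simulate_copy_set(P4B, 30, noise, rng, "c") + simulate_copy_set(
            P4, 30, noise, rng, "a"
        )
        parent = SubfamilyModel("Platy-1-4", None, P4)
        tree = derive_subfamilies(stack_aligned(copies, P4), parent)
        found = set()
        for node in tree.walk():
            found |= {d.position for d in node.diagnostics}
        tp += len(found & planted)
        fp += len(found - planted)
        fn += len(planted - found)
    assert tp / (tp + fn) >= 0.95
    assert tp / (tp + fp) >= 0.95
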