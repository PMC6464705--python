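"""Discover nested subfamilies from shared diagnostic substitutions.

Copies descending from a mutated master element share its substitutions
nonrandomly.  The module stacks copies on the parent consensus, finds columns
whose derived-base counts are binomially improbable under neutral noise,
groups co-segregating columns, and recursively partitions the copies -
recovering the six-substitution derived subfamily and its three-substitution
nested daughter, with field-convention names.
"""

import numpy as np

from platy1 import evolve_master, simulate_copy_set
from platy1.simulate import PLAN_4B, PLAN_4B3, PLAN_P4, ROOT_CONSENSUS_SYNTHETIC
from platy1.subfamilies import DeriveParams, SubfamilyModel, derive_subfamilies, stack_aligned

p4 = evolve_master(ROOT_CONSENSUS_SYNTHETIC, PLAN_P4)
p4b = evolve_master(p4, PLAN_4B)      # six diagnostic substitutions
p4b3 = evolve_master(p4b, PLAN_4B3)   # three additional ones

rng = np.random.default_rng(2019)
copies = simulate_copy_set(p4b, 58, 0.01, rng, "c4b") + simulate_copy_set(
    p4b3, 10, 0.01, rng, "c4b3"
)

parent = SubfamilyModel("Platy-1-4", None, p4)
parent.children.append(SubfamilyModel("Platy-1-4a", "Platy-1-4", p4))  # known sibling
tree = derive_subfamilies(stack_aligned(copies, p4), parent, DeriveParams(lineage="aotus"))

for node in tree.walk():
    diag = ", ".join(
        f"{d.position}{d.ancestral_base}>{d.derived_base}({d.substitution_class[:3]})"
        for d in node.diagnostics
    )
    print(f"{node.name:<22} {len(node.members):3d} members   {diag or '(root)'}")

# The child carries the six planted diagnostics (positions 19..82) and the
# nested daughter adds three more (12, 62, 100), shared by 10 of 68 copies.
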