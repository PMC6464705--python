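"""Summarise an insertion presence/absence genotype panel.

The simulated owl-monkey panel genotypes every owl-branch locus in 23
individuals: old insertions are fixed present, recent ones segregate at a
sampled allele frequency, and three loci are reciprocally fixed between the
red-necked and gray-necked groups - usable as group-diagnostic markers.
"""

from platy1 import simulate_dataset
from platy1.genotypes import classify_all, find_group_diagnostic_loci, summarize_panel
from platy1.simulate import SimulationConfig

ds = simulate_dataset(SimulationConfig(seed=7, ancestor_length=30_000))
table = ds.genotype_tables["owl"]
print(f"panel: {table.data.shape[0]} loci x {table.data.shape[1]} individuals\n")

print(summarize_panel(table).to_string(index=False), "\n")

cls = classify_all(table)
poly = cls[cls.label == "polymorphic"]
print("segregating loci and insertion allele frequencies:")
print(poly[["label", "frequency"]].round(3).to_string(), "\n")

diag = find_group_diagnostic_loci(table)
print("group-diagnostic loci (reciprocally fixed between groups):")
print(diag.to_string(index=False))

# A locus fixed present in every red-necked individual and absent in every
# gray-necked one separates the two owl monkey groups with a single PCR band.
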