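"""Shared fixtures: one default simulated dataset and its pipeline products.

The simulation and the genome scans are the expensive steps, so they are
session-scoped; tests must not mutate the shared objects.
"""

from __future__ import annotations

import warnings

import pytest

from platy1 import filter_full_length, scan_genome, simulate_dataset
from platy1.orthology import GenomeIndex


@pytest.fixture(scope="session")
def dataset():
    """The default study-condition simulation (4 species, ~50 insertions)."""
    return simulate_dataset()


@pytest.fixture(scope="session")
def pipeline(dataset):
    """Scan + full-length filter for every simulated genome."""
    genome_seqs = {
        sp: {rec.contig_id: rec.sequence} for sp, rec in dataset.genomes.items()
    }
    hits, loci = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp, rec in dataset.genomes.items():
            hits[sp] = scan_genome(rec, dataset.library)
            loci[sp] = filter_full_length(
                hits[sp], dataset.library, {sp: genome_seqs[sp]}
            )
    return {"hits": hits, "loci": loci, "genome_seqs": genome_seqs}


@pytest.fixture(scope="session")
def genome_indexes(dataset):
    return {sp: GenomeIndex([rec]) for sp, rec in dataset.genomes.items()}


def match_truth_locus(dataset, hit):
    """Truth position row overlapping a hit, or None."""
    pos = dataset.positions
    sub = pos[
        (pos.species == hit.genome_id)
        & (pos.elem_start < hit.end)
        & (pos.elem_end > hit.start)
    ]
    return sub.iloc[0] if len(sub) else None
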