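"""Shared fixtures: tiny hand-built genomes and a mid-sized synthetic one."""

import pytest

from homeoconf.io import GeneRecord, GenomeAnnotation, HomoeologPair, PairTable
from homeoconf.synthetic import SimulationConfig, generate


def make_annotation(spec):
    """Build an annotation from {scaffold: [(gene_id, subgenome), ...]} with
    genes laid out in list order at 1 kb spacing."""
    records = []
    for scaffold, genes in spec.items():
        for i, (gid, sub) in enumerate(genes):
            start = 1 + 1000 * i
            records.append(
                GeneRecord(gid, sub, scaffold, start, start + 500, "+")
            )
    return GenomeAnnotation.from_records(records)


def collinear_annotation(n, prefix1="a", prefix2="b"):
    """Two scaffolds of n genes each, same ancestral order."""
    return make_annotation(
        {
            "chrA": [(f"{prefix1}{i}", "A") for i in range(n)],
            "chrB": [(f"{prefix2}{i}", "B") for i in range(n)],
        }
    )


def collinear_pairs(n, distance=0.1, prefix1="a", prefix2="b"):
    return PairTable.from_pairs(
        [HomoeologPair(f"{prefix1}{i}", f"{prefix2}{i}", distance) for i in range(n)]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A quick structured simulation reused by several tests."""
    config = SimulationConfig(
        n_chromosomes=4,
        genes_per_chromosome=60,
        n_translocations=1,
        translocation_span=12,
        n_decoy_families=4,
        decoy_family_size=4,
        n_single_gene_scaffolds=4,
        seed=7,
    )
    return generate(config)


@pytest.fixture(scope="session")
def default_sim():
    """The full default-condition simulation (seed 42, ~2,000 pairs)."""
    return generate(SimulationConfig())
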