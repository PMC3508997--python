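from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tandemdup.genome_io import GeneRecord, PeptideRecord, build_gene_index
from tandemdup.synthetic import FixtureSpec, generate_genome


def make_genes(starts, chromosome="chr1", length=1000, prefix="g"):
    """Gene records at the given start coordinates, ids in input order."""
    return [
        GeneRecord(
            gene_id=f"{prefix}{i}",
            chromosome=chromosome,
            start=s,
            end=s + length - 1,
        )
        for i, s in enumerate(starts)
    ]


def pep(gene_id: str, sequence: str) -> PeptideRecord:
    return PeptideRecord(peptide_id=f"pep_{gene_id}", gene_id=gene_id, sequence=sequence)


@pytest.fixture(scope="session")
def small_genome():
    """A compact planted genome for stages that do not need genome scale."""
    spec = FixtureSpec(
        n_chromosomes=2, genes_per_chromosome=60, n_families=6, seed=11
    )
    return spec, generate_genome(spec)


@pytest.fixture(scope="session")
def small_index(small_genome):
    _spec, genome = small_genome
    return build_gene_index(genome.genes)
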