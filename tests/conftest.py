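"""Shared fixtures: small deterministic genomes and simulated species."""

from __future__ import annotations

import random

import pytest

from nucmorph.core import Chromosome, GeneModel, Genome
from nucmorph.gene_caller import call_genome
from nucmorph.simulate import SimParams, generate_ancestor, evolve_species


def random_dna(n: int, gc: float = 0.28, seed: int = 0, rng=None) -> str:
    r = rng or random.Random(seed)
    return "".join(
        r.choices("ACGT", weights=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], k=n)
    )


def make_genome(*seqs: str, species: str = "toy") -> Genome:
    return Genome(
        species=species,
        chromosomes=[
            Chromosome(id=f"chr{i + 1}", sequence=s) for i, s in enumerate(seqs)
        ],
    )


def make_gene(gid, chrom, exons, strand="+", category="function-predicted", **kw):
    return GeneModel(
        id=gid, chromosome_id=chrom, strand=strand, exons=list(exons),
        category=category, **kw,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated genome: 2 chromosomes of 40 kb."""
    params = SimParams(
        seed=11, n_chromosomes=2, chromosome_length=40_000,
        subtelomere_unit_length=3200,
    )
    return generate_ancestor(params)


@pytest.fixture(scope="session")
def default_sim():
    """The generator under its default study conditions."""
    return generate_ancestor(SimParams(seed=0))


@pytest.fixture(scope="session")
def default_called(default_sim):
    genome, _truth = default_sim
    return call_genome(genome)


@pytest.fixture(scope="session")
def evolved_pair(default_sim):
    """Ancestor plus a derived species with known events."""
    events = [
        ("substitute", {"rate": 0.02, "protein_rate": 0.02}),
        ("lose_genes", {"n": 4}),
        ("duplicate", {"n_genes": 2}),
        ("duplicate", {"n_genes": 3}),
        ("invert", {"n_genes": 5}),
        ("gain_intron", {"n": 2}),
        ("lose_intron", {"n": 2}),
    ]
    derived = evolve_species(default_sim, events, seed=77, species="spB")
    return default_sim, derived


def merged_families(*truths) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for t in truths:
        for fam, members in t.families.items():
            fams.setdefault(fam, []).extend(members)
    return fams
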