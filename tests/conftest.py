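"""Shared fixtures: small simulated histories reused across test modules."""

import pytest

import hexafrac as hf

GENOMES = ("A", "B", "C")
COPIES = ("LF", "MF1", "MF2")


@pytest.fixture(scope="session")
def ancestor_small():
    """A 10-gene reference region."""
    return hf.simulate_ancestral_region(10, mean_exons_per_gene=3,
                                        mean_exon_len=210,
                                        mean_intergenic_len=900, seed=11)


@pytest.fixture(scope="session")
def evolved_default(ancestor_small):
    """Default-parameter evolution of the small region (with fractionation)."""
    params = hf.EvolutionParams(seed=21)
    return hf.evolve_polyploid_genomes(ancestor_small, params)


@pytest.fixture(scope="session")
def evolved_lossless(ancestor_small):
    """Divergence without fractionation or rearrangement."""
    params = hf.EvolutionParams(seed=22, exon_del_prob_per_branch=0.0)
    return hf.evolve_polyploid_genomes(ancestor_small, params)


@pytest.fixture(scope="session")
def presence_default(ancestor_small, evolved_default):
    copies, _ = evolved_default
    ordered = [copies[(g, c)] for g in GENOMES for c in COPIES]
    return hf.build_presence_matrix(ancestor_small, ordered)


@pytest.fixture(scope="session")
def presence_lossless(ancestor_small, evolved_lossless):
    copies, _ = evolved_lossless
    ordered = [copies[(g, c)] for g in GENOMES for c in COPIES]
    return hf.build_presence_matrix(ancestor_small, ordered)
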