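import pytest

from wagoseq import SimConfig, build_index, build_transcript_index, generate_genome


def small_config(seed: int = 7) -> SimConfig:
    """A reduced study used by unit tests where absolute scale is irrelevant."""
    return SimConfig(
        seed=seed,
        contig_lengths={"chr1": 150_000, "chr2": 150_000},
        mito_length=5_000,
        n_genes=30,
        n_dispersed_planted=8,
        n_dispersed_cold=8,
        n_tandem=8,
        n_mirna=6,
        n_rrna=2,
        n_trna=4,
        depth=20_000,
    )


@pytest.fixture(scope="session")
def sim_small():
    return generate_genome(small_config())


@pytest.fixture(scope="session")
def small_indexes(sim_small):
    genome_index = build_index(sim_small.genome)
    tx_index = build_transcript_index(sim_small.annotations.genes, sim_small.genome)
    return genome_index, tx_index


@pytest.fixture(scope="session")
def sim_default():
    """The full-size default study (shared across the slower tests)."""
    return generate_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_indexes(sim_default):
    genome_index = build_index(sim_default.genome)
    tx_index = build_transcript_index(sim_default.annotations.genes, sim_default.genome)
    return genome_index, tx_index
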