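import pytest

from isochain import SimConfig, build_toy_locus, simulate_long_reads


@pytest.fixture(scope="session")
def toy():
    """Plus-strand toy locus (genome, annotation), seed 1."""
    return build_toy_locus(1)


@pytest.fixture(scope="session")
def toy_minus():
    """Mirror of the toy locus on the minus strand, same seed."""
    return build_toy_locus(1, strand="-")


@pytest.fixture(scope="session")
def noisy_sim(toy):
    """A mid-size noisy simulation shared by read-level tests."""
    genome, locus = toy
    cfg = SimConfig(n_long_reads=800, n_short_reads=4000, seed=7)
    reads, seqs, truth = simulate_long_reads(locus, genome, cfg)
    return cfg, reads, seqs, truth


@pytest.fixture(scope="session")
def clean_sim(toy):
    """A no-noise simulation: every read is an intact original molecule."""
    genome, locus = toy
    cfg = SimConfig(n_long_reads=300, dup_rate=0.0, truncation_rate=0.0,
                    artifact_rate=0.0, seed=5)
    reads, seqs, truth = simulate_long_reads(locus, genome, cfg)
    return cfg, reads, seqs, truth
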