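import pytest

from allelepipe.simulate import (
    DuplicationSpec,
    SimulationConfig,
    align_sample_reads,
    simulate_reads,
    simulate_sample,
)


@pytest.fixture(scope="session")
def dup_sample():
    """Fixture genome with an engineered paralog at one het SNV, reads
    simulated balanced (truth ratio 0.5 everywhere)."""
    cfg = SimulationConfig(
        genome_length=10_000,
        n_het_snvs=8,
        depth=200,
        seed=11,
        duplication=DuplicationSpec(),
    )
    sample = simulate_sample(cfg)
    simulate_reads(sample)
    return sample


@pytest.fixture(scope="session")
def dup_alignments(dup_sample):
    return align_sample_reads(dup_sample)


@pytest.fixture(scope="session")
def clean_sample():
    """Repeat-free, error-free balanced fixture."""
    cfg = SimulationConfig(genome_length=6_000, n_het_snvs=10, depth=40, seed=7)
    sample = simulate_sample(cfg)
    simulate_reads(sample)
    return sample


@pytest.fixture(scope="session")
def clean_alignments(clean_sample):
    return align_sample_reads(clean_sample)
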