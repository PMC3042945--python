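import numpy as np
import pytest

from gametotk import synthetic_data as sim


@pytest.fixture(scope="session")
def small_library():
    """A small error-free-ish simulated library shared across tests."""
    config = sim.SimConfig(
        n_genes=15,
        n_reads=250,
        seed=101,
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        adapter_5p_prob=0.5,
        adapter_3p_prob=0.5,
        polyA_prob=0.5,
    )
    transcripts = sim.simulate_transcriptome(config)
    reads, truth = sim.simulate_reads(transcripts, config)
    return config, transcripts, reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
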