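import numpy as np
import pytest

from circqtl import simulate


@pytest.fixture(scope="session")
def annotation():
    """Small shared genome/transcript/circRNA annotation."""
    return simulate.simulate_genome_and_annotation(
        seed=7, n_chrom=2, chrom_len=60_000, n_transcripts=6, n_circ=8)


@pytest.fixture(scope="session")
def genotypes():
    return simulate.simulate_genotypes(
        seed=7, n_samples=40, n_variants=30,
        region=("chr1", 1, 60_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
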