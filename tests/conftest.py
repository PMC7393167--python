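import numpy as np
import pytest

from isohap.genomic_io import Genome, GenomeSequence
from isohap.phasing import run_phasing
from isohap.simulate import (
    SimulationConfig,
    simulate_genome_and_genes,
    simulate_reads,
)


def make_genome(sequence: str, name: str = "chrT") -> Genome:
    return Genome({name: GenomeSequence(name, sequence)})


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation with the full phasing run (seeded)."""
    config = SimulationConfig(seed=1)
    truth = simulate_genome_and_genes(config)
    reads = simulate_reads(truth, config)
    result = run_phasing(
        truth.genome, reads.long_alignments, reads.short_pairs, reads.roi_to_isoform
    )
    return truth, reads, result


@pytest.fixture(scope="session")
def zero_error_sim():
    """Noiseless simulation (tiled coverage, no errors) with the phasing run."""
    config = SimulationConfig(seed=2).zero_error()
    truth = simulate_genome_and_genes(config)
    reads = simulate_reads(truth, config)
    result = run_phasing(
        truth.genome, reads.long_alignments, reads.short_pairs, reads.roi_to_isoform
    )
    return truth, reads, result


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
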