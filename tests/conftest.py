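import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from circsponge import detect as cd
from circsponge.sim import SimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def mini_cfg() -> SimConfig:
    """A small but complete study: 1 x 60 kb chromosome, 12 genes, 5 planted
    circRNAs, 2 sponge triplets, error-free reads."""
    return SimConfig(
        seed=5,
        n_chromosomes=1,
        chrom_length=60_000,
        n_genes=12,
        n_circ_exonic=3,
        n_circ_intronic=1,
        n_circ_intergenic=1,
        n_triplets=2,
        n_mirnas=5,
        background_depth=300,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def mini_sim(mini_cfg):
    genome, annotation, truth = simulate_genome(mini_cfg)
    return genome, annotation, truth


@pytest.fixture(scope="session")
def mini_reads(mini_cfg, mini_sim):
    genome, annotation, truth = mini_sim
    return simulate_reads(truth, genome, mini_cfg, annotation)


@pytest.fixture(scope="session")
def mini_index(mini_sim):
    genome, _, _ = mini_sim
    return cd.build_index(genome, 20)
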