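import pytest

from spacerscreen import attach_oligos, design_tiled_spacers
from spacerscreen.synthetic_data import SimGenomeConfig, make_genome


@pytest.fixture(scope="session")
def small_sim():
    """A 2 kb simulated genome with proportionally scaled operons."""
    cfg = SimGenomeConfig(length=2000, pe_start=100, pe_end=700, pl_start=700, pl_end=2000, seed=5)
    genome, regions = make_genome(cfg)
    return cfg, genome, regions


@pytest.fixture(scope="session")
def small_genome(small_sim):
    return small_sim[1]


@pytest.fixture(scope="session")
def small_designs(small_genome):
    return attach_oligos(design_tiled_spacers(small_genome))
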