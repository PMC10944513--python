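import pytest

from hybridzga.config import SimConfig
from hybridzga.dynamics import fpkm
from hybridzga.simulate import generate_expression_program, generate_genome_pair


@pytest.fixture(scope="session")
def cfg_small():
    return SimConfig(seed=11, n_gene_pairs=40)


@pytest.fixture(scope="session")
def gp_small(cfg_small):
    return generate_genome_pair(cfg_small)


@pytest.fixture(scope="session")
def prog_small(cfg_small, gp_small):
    return generate_expression_program(cfg_small, gp_small)


@pytest.fixture(scope="session")
def cfg_default():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def gp_default(cfg_default):
    return generate_genome_pair(cfg_default)


@pytest.fixture(scope="session")
def prog_default(cfg_default, gp_default):
    return generate_expression_program(cfg_default, gp_default)


@pytest.fixture(scope="session")
def fpkm_zero_noise(gp_small, prog_small):
    """Noise-free FPKM tables for both crosses of the small simulation."""
    lengths = gp_small.exonic_lengths()
    return {
        cross: fpkm(prog_small.expected_parent_counts(cross), lengths)
        for cross in ("forward", "reverse")
    }
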