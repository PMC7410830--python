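import pytest

from devdecomp.synthetic_data import (
    SynthConfig,
    generate_bulk_matrix,
    generate_epigenome,
    generate_sc_counts,
)

# scaled QC / feature-selection settings matching the synthetic data
# dimensions (400 genes, 5 x 200 cells); library defaults are full-scale
SC_QC = dict(min_genes=100, max_genes=380, max_mito=0.20, min_cell_frac=0.005)
SC_TOP_N = 100


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def bulk_data(config):
    return generate_bulk_matrix(config)


@pytest.fixture(scope="session")
def sc_data(config):
    return generate_sc_counts(config)


@pytest.fixture(scope="session")
def epigenome(config):
    return generate_epigenome(config)
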