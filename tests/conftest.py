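import pytest

from donorforge import fixtures as fx
from donorforge.params import DesignParameters
from donorforge.parts import PartsLibrary


@pytest.fixture(scope="session")
def params() -> DesignParameters:
    return DesignParameters()


@pytest.fixture(scope="session")
def library() -> PartsLibrary:
    return PartsLibrary()


@pytest.fixture(scope="session")
def mixed():
    """One 10-gene genome cycling through every designed gene architecture."""
    spec = fx.default_spec(seed=1, n_genes=10)
    return fx.generate_genome(spec)


@pytest.fixture(scope="session")
def genome(mixed):
    return mixed[0]


@pytest.fixture(scope="session")
def truth(mixed):
    return mixed[1]


@pytest.fixture(scope="session")
def designs(genome, truth, params):
    """Finished donor designs for every designable gene in the mixed genome."""
    from donorforge.pipeline import design_gene

    out = {}
    for row in truth.rows:
        if row.expected_strategy == "UNDESIGNABLE":
            continue
        out[row.gene_id] = design_gene(genome, row.gene_id, params)
    return out
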