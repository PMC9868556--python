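import warnings

import pytest

from lncforge.simulate import SimulationConfig, generate


SMALL = dict(
    seed=11,
    n_coding_genes=60,
    n_linc=50,
    n_sense=20,
    n_antisense=15,
    n_intronic=10,
    n_short=5,
    n_single_exon=30,
    n_long_orf_decoys=8,
    n_hexamer_decoys=8,
    n_known_ncrna=6,
    n_all_zero=4,
    n_de_up_S=10,
    n_de_up_R=12,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete synthetic study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(SimulationConfig(**SMALL))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)
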