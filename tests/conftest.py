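import numpy as np
import pytest

from apadel.synth_data import SimConfig, simulate_abundance, simulate_genome


@pytest.fixture(scope="session")
def sim():
    """A small shared simulation: genome, annotation, abundance and truth."""
    cfg = SimConfig(seed=11, n_genes=30, n_lengthening=6, n_shortening=3, a_stretch_fraction=1.0)
    genome, isoforms, truth = simulate_genome(cfg)
    abund, groups = simulate_abundance(truth, cfg)
    return {
        "cfg": cfg,
        "genome": genome,
        "isoforms": isoforms,
        "truth": truth,
        "abund": abund,
        "groups": groups,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
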