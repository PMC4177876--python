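import numpy as np
import pytest

from ffrp.motifs import Motif
from ffrp.synthetic_data import generate_world


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_motif(rng):
    def make(width=6, seed=None, alpha=1.0):
        r = rng if seed is None else np.random.default_rng(seed)
        return Motif(f"rand_w{width}", r.dirichlet(np.full(4, alpha), size=width).T)

    return make


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    return generate_world(
        n_genes=80,
        promoter_len=120,
        n_tfs=2,
        motif_width=8,
        regulon_fraction=0.2,
        n_arrays=80,
        n_conditions=4,
        n_species=3,
        n_ortho_proteins=8,
        seed=11,
    )
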