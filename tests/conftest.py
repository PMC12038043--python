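import numpy as np
import pandas as pd
import pytest

from gonadomics import SimDesign, simulate_multiome
from gonadomics.dataset import build_bundle


@pytest.fixture(scope="session")
def sim():
    """One default-design synthetic multiome shared across tests."""
    return simulate_multiome(SimDesign(seed=3))


@pytest.fixture(scope="session")
def bundle():
    """A full synthetic study bundle (ChIP, sequences, motifs, bulk DE)."""
    return build_bundle(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def qc_cells():
    """A 400-cell table with exactly 37 planted QC failures."""
    design = SimDesign(
        n_cells_per_cluster=(200, 200),
        n_genes=50,
        n_peaks=60,
        qc_fail_rates={"mito": 8, "ribo": 5, "hemo": 4, "n_genes": 5,
                       "frip": 6, "frag_low": 3, "frag_high": 2,
                       "blacklist": 4},
        seed=21,
    )
    out = simulate_multiome(design)
    assert len(out.cells) == 400
    return out.cells, out.truth["qc_failures"]
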