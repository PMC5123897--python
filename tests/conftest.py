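import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pchicstats import core_io as io
from pchicstats import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimConfig:
    return sd.SimConfig(seed=20260924)


@pytest.fixture(scope="session")
def fragment_map(sim_cfg):
    return sd.simulate_fragment_map(sim_cfg)


@pytest.fixture(scope="session")
def interactome(sim_cfg, fragment_map):
    """(interactions, reg_states, expression, gene_models, truth)."""
    return sd.simulate_interactome(sim_cfg, fragment_map)


@pytest.fixture(scope="session")
def haplotypes(sim_cfg):
    """(panel, recomb_map)."""
    return sd.simulate_haplotype_panel(sim_cfg)


@pytest.fixture()
def tiny_fragment_map():
    """Ten 1-kb fragments tiling a 10-kb chromosome."""
    table = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(10) * 1000,
        "end": (np.arange(10) + 1) * 1000,
        "frag_id": np.arange(10),
        "is_bait": [False, True, False, False, False, False, False, False, False, False],
    })
    return io.FragmentMap(table)


def make_peak_table(rows, cell_types):
    cols = ["baitChr", "baitStart", "baitEnd", "baitID", "baitName",
            "oeChr", "oeStart", "oeEnd", "oeID", "oeName", "dist", *cell_types]
    return pd.DataFrame(rows, columns=cols)
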