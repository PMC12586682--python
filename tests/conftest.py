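import numpy as np
import pytest

from meltid.amplicon import AmpliconRecord
from meltid.fixtures import make_panel
from meltid.meltsim import MeltModelParams, TemperatureGrid, simulate_melt


@pytest.fixture(scope="session")
def panel10():
    """Ten synthetic species, including the designated 4/12/1-nt close pairs."""
    return make_panel(10, seed=7)


@pytest.fixture(scope="session")
def noiseless_params():
    """Single-domain, jitter-free melt model with flat baselines."""
    return MeltModelParams(n_domains=1, noise_sd=0.0, amplitude_jitter_sd=0.0,
                           tm_jitter_sd=0.0, ds_baseline=(1000.0, 0.0),
                           ss_baseline=(100.0, 0.0))


@pytest.fixture(scope="session")
def grid():
    return TemperatureGrid()


@pytest.fixture(scope="session")
def noiseless_run(panel10, noiseless_params, grid):
    return simulate_melt(panel10[0], noiseless_params, grid, replicate_seed=1)


@pytest.fixture()
def gc_half_record():
    """A 50% GC amplicon with a clean single melting domain."""
    return AmpliconRecord(id="half", sequence="ATGC" * 40, species_label="half")
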