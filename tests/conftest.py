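import numpy as np
import pytest

from pepfinger.plate_io import WellRecord
from pepfinger.synthetic import CohortSpec, SimulationConfig, simulate_cohort, table2_enzyme

TIME_GRID = np.arange(0.0, 61.0, 5.0)


def make_well(values, well_id="W1", substrate="PepA", group="NONE", **kw):
    values = np.asarray(values, dtype=float)
    defaults = dict(
        sample_id="S1",
        sample_type="saliva",
        dilution_factor=20.0,
        time_min=TIME_GRID[: values.size],
    )
    defaults.update(kw)
    return WellRecord(
        well_id=well_id,
        substrate=substrate,
        inhibitor_group=group,
        fluorescence_au=values,
        **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210866)


@pytest.fixture(scope="session")
def single_enzyme_config():
    """Noise-free plate physics with 1 nM MMP-9 at the published efficiencies."""
    return SimulationConfig(enzymes=[table2_enzyme("MMP9", 1.0)])


@pytest.fixture(scope="session")
def small_cohort():
    """A small noise-free cohort at observable plate-reader gain."""
    cfg = SimulationConfig(gain_au_per_nM=100.0, seed=7)
    spec = CohortSpec(n_caries=8, n_healthy=6, seed=7)
    wells, truth = simulate_cohort(spec, cfg)
    return wells, truth
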