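import numpy as np
import pytest
from hypothesis import settings

from ctmeth.cm_scoring import CalibrationTable, build_calibration
from ctmeth.synthetic_data import NoiseModel, SpikeDesign, simulate_spike_replicates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plasma_calibration() -> CalibrationTable:
    """Calibration built from 11 simulated plasma replicates of 300 spiked copies."""
    runs, _ = simulate_spike_replicates(
        SpikeDesign(seed=999, copies_per_condition=(300.0,), replicates_per_condition=11)
    )
    return build_calibration(runs)


@pytest.fixture(scope="session")
def serum_calibration() -> CalibrationTable:
    runs, _ = simulate_spike_replicates(
        SpikeDesign(
            seed=998,
            copies_per_condition=(300.0,),
            replicates_per_condition=11,
            matrix="serum",
        ),
        noise=NoiseModel.serum(),
    )
    return build_calibration(runs)


@pytest.fixture()
def flat_calibration() -> CalibrationTable:
    """Hand-set calibration: every gene median 3.0, censoring bound 16.0."""
    from ctmeth.core_model import DEFAULT_PANEL

    return CalibrationTable(
        median_delta_ct_300={g: 3.0 for g in DEFAULT_PANEL.targets}, censor_offset=13.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
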