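import dataclasses

import numpy as np
import pytest

from microgt.simulate import (
    CalciumKernel,
    CohortConfig,
    GroupSpec,
    ModuleStructure,
    SpikeTrainModel,
    paper_like_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Two small groups, enough to exercise every pipeline stage quickly."""
    wt = GroupSpec(
        label="ctrl",
        n_sessions=1,
        neurons_per_session=12,
        spikes=SpikeTrainModel(mode="poisson", base_rate=0.3),
        modules=ModuleStructure(n_modules=2, shared_drive_strength=0.5),
        kernel=CalciumKernel(decay=0.95, unit_amplitude=0.3, baseline=1.0, noise_sd=0.03),
    )
    dis = dataclasses.replace(
        wt,
        label="model",
        spikes=SpikeTrainModel(
            mode="burst",
            base_rate=0.1,
            burst_entry_prob=0.002,
            burst_rate=3.0,
            burst_mean_length=30.0,
            bursty_fraction=0.25,
        ),
        kernel=CalciumKernel(decay=0.95, unit_amplitude=0.21, baseline=1.0, noise_sd=0.03),
    )
    return CohortConfig(groups=(wt, dis), duration=1500, frame_rate=30.0, seed=7)


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-scale simulated cohort, shared across tests that need it."""
    from microgt.simulate import generate_cohort

    return generate_cohort(paper_like_config(seed=1))
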