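import numpy as np
import pytest

import ceatopo as ct


@pytest.fixture
def noiseless_sigmoid_cohort():
    """Ten pure-sigmoid responders, no noise, event at 120-180 s."""
    spec = ct.TraceCohortSpec(
        n_neurons=10,
        duration=240.0,
        noise_sd=0.0,
        responder_mix={"sigmoid": 1.0},
        sigmoid_params=(1.0, 0.2, 30.0, 0.0),
        event_plan=(("stim", 120.0, 180.0),),
        seed=0,
    )
    return ct.generate_trace_dataset(spec)


@pytest.fixture
def two_block_cohort():
    """Noiseless tracing cohort with one rostral and one caudal cluster."""
    spec = ct.TopographyCohortSpec(
        n_subjects=12,
        n_regions=8,
        cluster_plan=(
            (("SPFp", "BLAa", "SSs"), "rostral", 0.9),
            (("VISC", "PB", "BLAp"), "caudal", 0.9),
        ),
        count_noise="none",
        seed=3,
    )
    return ct.generate_tracing_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
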