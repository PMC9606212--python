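import numpy as np
import pytest

from shearwalk import SynthConfig, VelocityDistribution, synth_trajectories

# Study conditions: alpha=3.8, v_min=5e-3 m/s, v_moy=1e-3 m/s.
ALPHA, V_MIN, V_MOY = 3.8, 5e-3, 1e-3
MEMORY_TIME = 0.5e-3
FINE_DT = 1e-5


@pytest.fixture(scope="session")
def dist6() -> VelocityDistribution:
    """The reference distribution with solved normalization constants."""
    return VelocityDistribution.from_constraints(ALPHA, V_MIN, V_MOY)


@pytest.fixture(scope="session")
def medium_ensemble(dist6):
    """Renewal ensemble at the recording protocol's scale: 200 platelets,
    1 s at 10 us sampling, 0.5 ms velocity memory."""
    config = SynthConfig(
        dist=dist6,
        memory_time=MEMORY_TIME,
        fine_dt=FINE_DT,
        duration=1.0,
        N=200,
        L=50e-6,
        seed=1234,
    )
    return synth_trajectories(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
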