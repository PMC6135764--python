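import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import loomassay as la

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def etho_cfg():
    return la.EthogramConfig()


@pytest.fixture(scope="session")
def small_arena():
    """Reduced-resolution 30 mm arena used for rendered fixtures."""
    return la.ArenaConfig(diameter_mm=30.0, frame_rate=60.0, image_size=(276, 260))


@pytest.fixture(scope="session")
def walking_fly():
    """A 10 s simulated walk with ground truth (no stimuli)."""
    return la.simulate_fly(la.AgentParams(), None, 10.0, seed=7)


@pytest.fixture(scope="session")
def looming_session():
    """One full 10 min open-loop looming session with ground truth."""
    schedule = la.build_schedule("open_loop_looming")
    traj, gt = la.simulate_fly(la.AgentParams(), schedule, 600.0, seed=11)
    return traj, gt
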