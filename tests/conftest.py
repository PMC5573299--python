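import numpy as np
import pytest

from graspdecode.sim_kinematics import KinSimConfig, simulate_reach_trial


@pytest.fixture(scope="session")
def noiseless_pair():
    """One noiseless trial per condition with default landmarks."""
    cfg = KinSimConfig(marker_noise_sd=0.0, seed=1)
    rng = np.random.default_rng(0)
    return cfg, {
        cond: simulate_reach_trial(cfg, cond, rng)
        for cond in ("individual", "social")
    }


@pytest.fixture(scope="session")
def minjerk_trial():
    """Noiseless, uncalibrated trial whose speed profile carries the exact
    minimum-jerk landmarks for D = 300 mm, MT = 600 ms."""
    cfg = KinSimConfig(
        marker_noise_sd=0.0, base_movement_time_individual=600.0,
        calibrate=False, seed=0,
    )
    rng = np.random.default_rng(0)
    return cfg, simulate_reach_trial(cfg, "individual", rng)
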