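import dataclasses

import numpy as np
import pytest

from prehension.mocap_io import Condition, MarkerTrajectory, Trial
from prehension.synthetic_data import SimulationConfig, TrialParams, simulate_reach


def make_trajectory(positions, sample_rate=100.0, marker_id="m", valid=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    times = np.arange(n) * 1000.0 / sample_rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return MarkerTrajectory(marker_id, times, positions, np.asarray(valid), sample_rate)


def make_trial(thumb, index, middle, **kwargs):
    cond = kwargs.pop("condition", Condition("matte", "empty", "visible"))
    return Trial(
        participant_id=kwargs.pop("participant_id", "P01"),
        block=kwargs.pop("block", 1),
        condition=cond,
        trajectories={"thumb": thumb, "index": index, "middle": middle},
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_config():
    return dataclasses.replace(
        SimulationConfig(), marker_noise_sd=0.0, dropout_rate=0.0
    )


@pytest.fixture
def noise_free_trial(noise_free_config):
    """One noise-free filled-cup trial with its ground truth."""
    cfg = noise_free_config
    params = TrialParams(
        participant_id="P01",
        block=1,
        condition=Condition("matte", "filled", "visible"),
        duration_ms=1640.0,
        adjustment_ms=1024.0,
        transport_peak=657.46,
        mga_mm=119.61,
        mga_rel=61.67,
        deviation_mm=-16.57,
        cup=cfg.cup_for("filled"),
        trial_id="nf1",
    )
    return simulate_reach(params, cfg, np.random.default_rng(0))
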