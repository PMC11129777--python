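import logging

import numpy as np
import pytest

from laminarid import AnalysisConfig, GroundTruth, simulate_session

logging.getLogger("laminarid").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_gt() -> GroundTruth:
    """Ground truth scaled to a 64-channel (620 µm span) probe."""
    return GroundTruth(
        seed=11,
        sink_depth_um=300.0,
        sink_width_um=80.0,
        flip_depth_um=340.0,
        n_units=40,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_gt):
    """Small but complete session: 12 flashes, 40 s, 64 channels."""
    return simulate_session(
        tiny_gt, n_trials=12, iti_s=2.0, duration_s=40.0, n_channels=64
    )


@pytest.fixture(scope="session")
def tiny_cfg() -> AnalysisConfig:
    return AnalysisConfig(analysis_minutes=40.0 / 60.0, min_spikes_per_cell=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
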