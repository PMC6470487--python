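"""Shared fixtures: small synthetic trials generated once per session."""

import numpy as np
import pytest

from gaitkine.synthetic_gait import GaitScenario, SensorErrorModel, generate


@pytest.fixture(scope="session")
def walk_trial():
    """30 s clean walk (cadence 120, 1.4 m/s), with ground truth."""
    return generate(GaitScenario.walk(duration=30.0, seed=7))


@pytest.fixture(scope="session")
def noisy_walk_trial():
    """60 s walk with the full sensor error model."""
    return generate(GaitScenario.walk(duration=60.0, seed=7,
                                      error_model=SensorErrorModel()))


@pytest.fixture(scope="session")
def run_trial():
    """30 s clean run (cadence 172, 5 m/s)."""
    return generate(GaitScenario.run(duration=30.0, seed=11))


@pytest.fixture(scope="session")
def walk_segmented(walk_trial):
    """Anatomical series (filtered vertical velocity) + segments of walk_trial."""
    from gaitkine.segmentation import segment_trial

    stream, _, _, _ = walk_trial
    anat, segs = segment_trial(stream)
    return anat, segs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
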