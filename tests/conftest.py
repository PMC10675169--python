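import numpy as np
import pytest

from posturekit.frame_encoding import FrameDataset
from posturekit.sensor_io import SENSOR_ORDER, SAMPLE_RATE_HZ, SynchronizedRecording
from posturekit.synthetic_motion import (
    MotionModelConfig,
    ScriptSegment,
    generate_balanced_dataset,
    session_recording,
    simulate_session,
)


def make_recording(data: np.ndarray, start: float = 0.0) -> SynchronizedRecording:
    return SynchronizedRecording(start_time=start, rate=SAMPLE_RATE_HZ, data=data)


@pytest.fixture
def zero_recording() -> SynchronizedRecording:
    """Three seconds of silence from all seven sensors."""
    return make_recording(np.zeros((len(SENSOR_ORDER), 150, 6)))


@pytest.fixture(scope="session")
def sim_session():
    """A 10-second scripted session: sitting with right-hand movement, then walking."""
    script = [
        ScriptSegment(duration=6, posture="SI", extremities=frozenset({"RH"})),
        ScriptSegment(duration=4, posture="WA", extremities=frozenset({"RL", "LL"})),
    ]
    streams, truth = simulate_session(script, MotionModelConfig(seed=11))
    return streams, truth


@pytest.fixture(scope="session")
def sim_recording(sim_session) -> SynchronizedRecording:
    streams, _ = sim_session
    return session_recording(streams)


@pytest.fixture(scope="session")
def balanced_208() -> FrameDataset:
    """Small balanced dataset: four windows per admissible combination."""
    return generate_balanced_dataset(MotionModelConfig(seed=5), n_windows=208)
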