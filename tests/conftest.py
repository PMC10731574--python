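import numpy as np
import pytest

from reachcomp import ChainConfig, MarkerName, Side, Task, TrialRecording


def make_trial(
    task: Task,
    displacements: dict[MarkerName, tuple[float, float, float]],
    n_frames: int = 12,
    rate: float = 60.0,
    side: Side = Side.RIGHT,
    base: float = 100.0,
    **kwargs,
) -> TrialRecording:
    """Build a trial where each listed marker moves linearly by the given
    (dx, dy, dz); all other required markers are present and stationary."""
    from reachcomp import required_markers

    ramp = np.linspace(0.0, 1.0, n_frames)[:, None]
    positions = {}
    markers = set(required_markers(task, side)) | set(displacements)
    for k, m in enumerate(sorted(markers, key=lambda x: x.value)):
        start = np.full(3, base + 10.0 * k)
        delta = np.asarray(displacements.get(m, (0.0, 0.0, 0.0)), dtype=float)
        positions[m] = start + ramp * delta
    return TrialRecording(
        positions=positions,
        sampling_rate=rate,
        task=task,
        reaching_side=side,
        **kwargs,
    )


@pytest.fixture
def chain() -> ChainConfig:
    return ChainConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
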