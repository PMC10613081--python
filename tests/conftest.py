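import numpy as np
import pytest

from echomotion.geometry import SegmentPartition
from echomotion.simulate import PhantomSpec, simulate_clip


@pytest.fixture(scope="session")
def uniform_clip():
    """Phantom with identical amplitude on every segment, no noise."""
    return simulate_clip(PhantomSpec(base_amplitudes=(5.0,) * 6), clip_id="uniform")


@pytest.fixture(scope="session")
def lesioned_clip():
    """Phantom whose segment 2 is fully akinetic (lesion factor 0)."""
    spec = PhantomSpec(lesion_segments=frozenset({2}), lesion_factor=0.0)
    return simulate_clip(spec, mi=True, clip_id="lesioned")


@pytest.fixture(scope="session")
def static_clip():
    """Phantom with zero motion everywhere."""
    return simulate_clip(PhantomSpec(base_amplitudes=(0.0,) * 6), clip_id="static")


def make_partition(points: np.ndarray, frame_index: int = 0) -> SegmentPartition:
    """Build a partition directly from a (6, N, 2) point array."""
    points = np.asarray(points, dtype=float)
    return SegmentPartition(
        points=points,
        segment_ids=(1, 2, 3, 5, 6, 7),
        span_bounds=np.linspace(0, 7, 8),
        frame_index=frame_index,
    )
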