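import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fruitsize as fs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def htc():
    """The phone profile used throughout: 3.81 mm focal length, 2.377 um pitch,
    4224x3136 sensor captured at 1920x1080."""
    return fs.HTC_DESIRE_820


@pytest.fixture(scope="session")
def bench_cam(htc):
    """Same optics binned to 960x540 — cheap renders for unit tests."""
    return htc.at_capture_resolution(960, 540)


@pytest.fixture(scope="session")
def bench_config(bench_cam):
    return fs.PipelineConfig(intrinsics=bench_cam)


@pytest.fixture(scope="session")
def default_scene(bench_cam):
    """Noiseless, untilted mango scene at 200 mm with a 40 mm fiducial."""
    return fs.render(fs.RenderParams(), bench_cam)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    union = np.logical_or(mask_a, mask_b).sum()
    return np.logical_and(mask_a, mask_b).sum() / union if union else 1.0


@pytest.fixture(scope="session")
def iou_fn():
    return iou
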