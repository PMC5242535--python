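import numpy as np
import pytest

from neuropheno.synthetic import (
    default_phantom_spec,
    default_trajectory_config,
)


@pytest.fixture(scope="session")
def spec():
    return default_phantom_spec()


@pytest.fixture(scope="session")
def traj():
    return default_trajectory_config()


@pytest.fixture(scope="session")
def wt_phantom_36(spec, traj):
    from neuropheno.synthetic import generate_phantom

    return generate_phantom(spec, 36, traj, "WT", "M")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_blob_2d(shape=(96, 96), center=(48, 48), radii=(22, 15), bump=True):
    """Asymmetric smooth test image for registration tests."""
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    img = np.clip(
        1 - (((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2),
        0, None) ** 1.5
    if bump:
        img += 0.5 * np.clip(
            1 - (((yy - center[0] + 10) / 6) ** 2 + ((xx - center[1] - 8) / 6) ** 2),
            0, None) ** 1.5
    return img
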