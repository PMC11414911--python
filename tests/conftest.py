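import numpy as np
import pytest

from mitotopo import Bifiltration, GrayscaleImage, worked_example_image


@pytest.fixture(scope="session")
def worked_example() -> GrayscaleImage:
    return worked_example_image()


@pytest.fixture()
def worked_bif(worked_example) -> Bifiltration:
    return Bifiltration(worked_example, max_i=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def brute_force_opening_white(white: np.ndarray, k: int) -> np.ndarray:
    """Independent opening oracle: union of all all-white k x k windows.

    Outside the frame counts as white, hence the white padding.
    """
    h, w = white.shape
    pad = np.pad(white, k, constant_values=True)
    out = np.zeros_like(pad, dtype=bool)
    for r in range(pad.shape[0] - k + 1):
        for c in range(pad.shape[1] - k + 1):
            if pad[r : r + k, c : c + k].all():
                out[r : r + k, c : c + k] = True
    return out[k : k + h, k : k + w]
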