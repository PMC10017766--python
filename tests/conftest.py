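import numpy as np
import pytest

from myoscaffold import LineScanProfile
from myoscaffold.synthetic import LineScanTruth, generate_linescan


@pytest.fixture
def noiseless_truth() -> LineScanTruth:
    return LineScanTruth(noise_sd=0.0)


@pytest.fixture
def noiseless_profile(noiseless_truth) -> LineScanProfile:
    profile, _ = generate_linescan(noiseless_truth)
    return profile


def make_profile(position, red, green=None) -> LineScanProfile:
    red = np.asarray(red, dtype=float)
    if green is None:
        green = red.copy()
    return LineScanProfile(np.asarray(position, dtype=float), red,
                           np.asarray(green, dtype=float))
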