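import numpy as np
import pytest

from lowdose.calibration import build_calibration
from lowdose.phantom_model import SyntheticPhantomSpec, generate_phantom

MAS_GRID = (0.6, 0.8, 1.2, 1.6, 2.0)
KVP_GRID = (80.0, 100.0, 120.0)


@pytest.fixture(scope="session")
def cal_grid():
    """The 3 kVp x 5 mAs calibration grid, one phantom per setting."""
    imgs = [
        generate_phantom(
            SyntheticPhantomSpec(
                height=256, width=256, kvp=k, mas=m, seed=int(k) * 100 + int(m * 10)
            )
        )
        for k in KVP_GRID
        for m in MAS_GRID
    ]
    return build_calibration(imgs)


@pytest.fixture(scope="session")
def cal_100():
    """A denser mAs ladder at 100 kVp with precise (512^2) slopes."""
    imgs = [
        generate_phantom(SyntheticPhantomSpec(kvp=100.0, mas=m, seed=int(m * 10)))
        for m in (0.5, 0.6, 0.8, 1.0, 1.2, 1.6, 2.0)
    ]
    return build_calibration(imgs)


@pytest.fixture(scope="session")
def phantom512():
    return generate_phantom(SyntheticPhantomSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
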