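import numpy as np
import pytest

from boldvar.variability import SubjectScan


@pytest.fixture
def rng():
    return np.random.default_rng(20230912)


@pytest.fixture
def small_scan(rng):
    """Random 5x5x5x40 scan with an irregular mask and positive mean."""
    shape = (5, 5, 5, 40)
    data = 100.0 + rng.standard_normal(shape)
    mask = rng.random(shape[:3]) > 0.3
    mask[0, 0, 0] = True  # never empty
    return SubjectScan(data=data, mask=mask, affine=np.diag([4.0, 4.0, 4.0, 1.0]),
                       subject_id="sub-0001")
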