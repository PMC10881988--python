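import numpy as np
import pytest

import prmsrs as P


@pytest.fixture
def pcfg():
    return P.PreprocessConfig()


@pytest.fixture
def grid(pcfg):
    return pcfg.grid()


@pytest.fixture
def narrow_ref(pcfg, grid):
    """Unit-norm reference with narrow, compactly supported peaks.

    Peaks sit >60 cm^-1 from both grid edges so +-30 cm^-1 shifts never
    clip support, and widths are small enough that the spectrum
    decorrelates within one grid step relative to the default penalty.
    """
    raw = P.make_reference([(1.0, 2900.0, 4.0), (0.5, 2960.0, 5.0)], grid, "narrow")
    return P.preprocess_pixel(raw, pcfg)


@pytest.fixture
def library():
    return P.make_library()


def shift_vector(v: np.ndarray, k: int) -> np.ndarray:
    """Displace v by k grid positions, zero-padding the vacated side."""
    out = np.zeros_like(v)
    if k > 0:
        out[k:] = v[:-k]
    elif k < 0:
        out[:k] = v[-k:]
    else:
        out[:] = v
    return out
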