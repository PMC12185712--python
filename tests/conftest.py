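import numpy as np
import pytest

from bcghr.hrpipe import HREstimate, HRSeries
from bcghr.synthgen import NoiseSpec, ZERO_NOISE


TILTED = np.array([0.6, 0.48, 0.64])  # arbitrary unit orientation


@pytest.fixture
def zero_noise():
    return ZERO_NOISE


@pytest.fixture
def default_noise():
    return NoiseSpec()


def series_from_fn(bpm_fn, t_start=10.0, t_end=130.0, hop=1.0, window_s=10.0,
                   confident_fn=None):
    """Build an HRSeries by sampling a bpm(t) function on a uniform hop grid."""
    times = np.arange(t_start, t_end + 1e-9, hop)
    ests = tuple(
        HREstimate(
            time=float(t),
            bpm=float(bpm_fn(t)),
            peak_magnitude=1.0,
            confident=True if confident_fn is None else bool(confident_fn(t)),
        )
        for t in times
    )
    return HRSeries(ests, window_s=window_s)
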