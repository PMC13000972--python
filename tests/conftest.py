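import numpy as np
import pytest

from windfleck import IrradianceSeries


def make_triangle_series(
    baseline=100.0,
    amplitude=100.0,
    base_s=0.2,
    start_s=1.0,
    total_s=3.0,
    rate=100.0,
):
    """Flat baseline with one symmetric triangular pulse (exactly on-grid)."""
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    v = np.full(n, float(baseline))
    half = int(round(base_s * rate / 2))
    si = int(round(start_s * rate))
    ramp = np.concatenate(
        (np.linspace(0, 1, half + 1), np.linspace(1, 0, half + 1)[1:])
    )
    v[si: si + 2 * half + 1] += amplitude * ramp
    return IrradianceSeries(t, v, rate=rate)


@pytest.fixture
def triangle_series():
    return make_triangle_series()


@pytest.fixture
def full_zone():
    def _mk(h=8, w=8):
        return np.ones((h, w), dtype=bool)

    return _mk
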