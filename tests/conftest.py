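import numpy as np
import pytest

from rodcoords.geometry import CoordinateParameters


@pytest.fixture
def straight_params():
    """Horizontal midline at y = 5 from x = 1 to 9, radius 2."""
    return CoordinateParameters(a0=5.0, a1=0.0, a2=0.0, xl=1.0, xr=9.0, r=2.0)


@pytest.fixture
def curved_params():
    return CoordinateParameters(a0=10.0, a1=0.1, a2=0.01, xl=2.0, xr=30.0, r=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cell_params(seed: int) -> CoordinateParameters:
    """A random but well-formed cell used by oracle sweeps."""
    r = np.random.default_rng(seed)
    a1 = r.uniform(-0.4, 0.4)
    a2 = r.uniform(-0.015, 0.015)
    xl = r.uniform(0.0, 6.0)
    xr = xl + r.uniform(6.0, 30.0)
    a0 = r.uniform(8.0, 20.0)
    return CoordinateParameters(a0=a0, a1=a1, a2=a2, xl=xl, xr=xr, r=r.uniform(2.0, 6.0))


def brute_force_closest(params, xp, yp, span=20.0, step=2e-3):
    """Grid minimiser of the point-to-midline distance with parabolic refinement."""
    x = np.arange(params.xl - span, params.xr + span, step)
    d2 = (x - xp) ** 2 + (params.p(x) - yp) ** 2
    i = int(np.argmin(d2))
    if 0 < i < len(x) - 1:
        y0, y1, y2 = d2[i - 1], d2[i], d2[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            return float(np.clip(x[i] + 0.5 * step * (y0 - y2) / denom,
                                 params.xl, params.xr))
    return float(np.clip(x[i], params.xl, params.xr))
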