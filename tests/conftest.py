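import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rgcdipoles import PointMosaic
from rgcdipoles.pipp import _hex_lattice

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def clipped_hex_lattice(window, lattice_const):
    """Hexagonal lattice points strictly inside *window*."""
    pts = _hex_lattice(window, lattice_const, 0.0)
    x0, x1, y0, y1 = window
    keep = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
            & (pts[:, 1] >= y0) & (pts[:, 1] <= y1))
    return pts[keep]


@pytest.fixture
def hex_points():
    return clipped_hex_lattice


@pytest.fixture
def csr_mosaic():
    """Factory for completely-spatially-random ON/OFF mosaics."""

    def make(seed, n_on=70, n_off=70, side=1000.0):
        rng = np.random.default_rng(seed)
        return PointMosaic(rng.random((n_on, 2)) * side,
                           rng.random((n_off, 2)) * side,
                           (0.0, side, 0.0, side))

    return make
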