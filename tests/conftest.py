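import numpy as np
import pytest

from mcfperc.geometry import FibrilDomain, Platelet


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def domain50():
    return FibrilDomain(50.0, 1000.0)


def make_cube(pid=0, center=(0.0, 0.0, 0.0), half=0.5, R=None):
    return Platelet(
        pid,
        np.asarray(center, float),
        np.array([half, half, half]),
        np.eye(3) if R is None else R,
    )


@pytest.fixture
def cube():
    return make_cube


def rot_about(axis: str, deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "W":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
    if axis == "T":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], float)
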