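"""Shared fixtures: small deterministic volumes and projectors.

Expensive objects (160-box volumes and their cached Fourier transforms)
are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from tubelattice.geometry import DensityVolume, FourierProjector
from tubelattice.synthetic_data import (
    DEFAULT_OPTICS,
    TubeLatticeSpec,
    build_lattice_volume,
    build_membrane_volume,
)

APIX = 4.0
BOX = 160


@pytest.fixture(scope="session")
def default_spec():
    return TubeLatticeSpec()


@pytest.fixture(scope="session")
def optics():
    return DEFAULT_OPTICS


@pytest.fixture(scope="session")
def membrane_volume(default_spec):
    return build_membrane_volume(default_spec, BOX, APIX)


@pytest.fixture(scope="session")
def membrane_projector(membrane_volume):
    return FourierProjector(membrane_volume)


@pytest.fixture(scope="session")
def stacked_volume(default_spec):
    vol, sites = build_lattice_volume(default_spec, "stacked", BOX, APIX, seed=3)
    return vol, sites


@pytest.fixture(scope="session")
def relaxed_volume(default_spec):
    vol, sites = build_lattice_volume(default_spec, "relaxed", BOX, APIX, seed=3)
    return vol, sites


@pytest.fixture(scope="session")
def stacked_projector(stacked_volume):
    return FourierProjector(stacked_volume[0])


@pytest.fixture(scope="session")
def relaxed_projector(relaxed_volume):
    return FourierProjector(relaxed_volume[0])


def ncc(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


def angular_error(a, b, period=360.0):
    d = abs(a - b) % period
    return min(d, period - d)
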