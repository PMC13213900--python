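"""Shared fixtures: analytic grids are cached per session (deterministic)."""

import numpy as np
import pytest

from piholescan.fixtures import (
    axial_depletion_fixture,
    blocked_axis_fixture,
    bump_on_monopole_fixture,
    fixture_suite,
    make_grids,
    toy_complex,
)


@pytest.fixture(scope="session")
def depletion_fixture():
    return axial_depletion_fixture()


@pytest.fixture(scope="session")
def depletion_grids(depletion_fixture):
    return make_grids(depletion_fixture)


@pytest.fixture(scope="session")
def bump_fixture():
    return bump_on_monopole_fixture()


@pytest.fixture(scope="session")
def bump_grids(bump_fixture):
    return make_grids(bump_fixture)


@pytest.fixture(scope="session")
def blocked_fixture():
    return blocked_axis_fixture()


@pytest.fixture(scope="session")
def blocked_grids(blocked_fixture):
    return make_grids(blocked_fixture)


@pytest.fixture(scope="session")
def suite_with_grids():
    """All analytic fixtures with their default-spacing grids."""
    return [(fx, *make_grids(fx)) for fx in fixture_suite()]


@pytest.fixture
def square_complex():
    return toy_complex()


def dense_axial_local_maxima(spec, z_lo=0.3, z_hi=3.0, step=0.001):
    """Independent 1-D oracle: local maxima of the analytic axial ESP.

    Evaluates the analytic field (not the grid) on a dense axial
    lattice and returns the z of every interior local maximum.  The
    scan starts above the near-charge clamp plateau (0.1 Å) so the
    plateau edge is not reported as a feature.
    """
    zs = np.arange(z_lo, z_hi + step / 2, step)
    pts = np.zeros((len(zs), 3))
    pts[:, 2] = zs
    v = spec.esp_at(pts)
    is_max = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return zs[1:-1][is_max]
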