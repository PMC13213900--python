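"""Analytic benchmark fixtures: toy complexes with known ESP structure.

Each fixture pairs a minimal four-donor "complex" with an analytic
:class:`~piholescan.espfield.FieldSpec` whose axial ESP profile is known
in closed form, so detector output can be checked against dense
one-dimensional oracles.  These fields emulate the qualitative shape of
a cationic complex's ESP — an overall positive Coulombic envelope with
a localized axial enhancement (or none) — not any specific quantum
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .chemio import Molecule, ScalarGrid
from .constants import DEFAULT_GRID_SPACING_BOHR
from .espfield import (
    FieldSpec,
    GridRequest,
    gaussian_density,
    grid_request_for_points,
    point_charge_field,
)

__all__ = [
    "Fixture",
    "toy_complex",
    "axial_depletion_fixture",
    "blocked_axis_fixture",
    "bump_on_monopole_fixture",
    "mirror_bump_fixture",
    "fixture_suite",
    "make_grids",
]

# Geometry of the toy complex: four donor nitrogens on a square of this
# circumradius (Å) with the metal at the centre.
DONOR_RADIUS = 2.06


@dataclass
class Fixture:
    name: str
    molecule: Molecule
    spec: FieldSpec
    expected_z: float | None  # analytic axial-maximum position, +z side


def toy_complex(metal: str = "Zn", donor_radius: float = DONOR_RADIUS
                ) -> Molecule:
    """Square-planar four-nitrogen toy complex with tagged roles."""
    coords = [
        [donor_radius, 0.0, 0.0],
        [0.0, donor_radius, 0.0],
        [-donor_radius, 0.0, 0.0],
        [0.0, -donor_radius, 0.0],
        [0.0, 0.0, 0.0],
    ]
    roles = {0: "donor_N", 1: "donor_N", 2: "donor_N", 3: "donor_N",
             4: "metal"}
    return Molecule(["N", "N", "N", "N", metal], np.array(coords),
                    roles=roles, charge=2, multiplicity=1)


def _cation_charges(mol: Molecule, metal_q: float = 2.0,
                    donor_q: float = -0.4) -> list:
    charges = []
    for i in mol.donor_indices:
        charges.append((donor_q, mol.coords[i].copy()))
    charges.append((metal_q, mol.coords[mol.metal_index].copy()))
    return charges


def _axial_coulomb_slope(charges, z: float) -> float:
    """dV/dz of the point-charge part on the +z axis (analytic)."""
    from .constants import COULOMB_K

    slope = 0.0
    for q, pos in charges:
        dx, dy, dz = -pos[0], -pos[1], z - pos[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        slope += -COULOMB_K * q * dz / r**3
    return slope


def axial_depletion_fixture(z_hole: float = 2.1, amp: float = 80.0,
                            width: float = 0.25) -> Fixture:
    """Cation with a constructed axial ESP maximum at exactly ``z_hole``.

    A +2 charge at the metal and four −0.4 charges at the donors give a
    decaying positive envelope; a narrow positive Gaussian is centred
    slightly above ``z_hole`` so that the total axial derivative
    vanishes exactly at ``z_hole`` (solved analytically), placing the
    ground-truth maximum in the experimentally relevant 1.8–2.4 Å band.
    """
    mol = toy_complex()
    charges = _cation_charges(mol)
    coulomb_slope = _axial_coulomb_slope(charges, z_hole)  # < 0

    def resid(c):
        d = c - z_hole
        return amp * d / width**2 * np.exp(-d * d / (2 * width**2)) + coulomb_slope

    center = brentq(resid, z_hole + 1e-6, z_hole + width)
    spec = FieldSpec(
        charges=charges,
        gaussians=[(amp, np.array([0.0, 0.0, center]), width)],
        density_gaussians=[(1.0, np.zeros(3), 1.0)],
    )
    return Fixture("axial_depletion", mol, spec, expected_z=z_hole)


def blocked_axis_fixture() -> Fixture:
    """Cation whose axial profile is strictly decreasing (no π-hole).

    Mimics an axially blocked complex: the positive feature sits well
    off-axis, so no on-axis local maximum exists anywhere in the search
    range.
    """
    mol = toy_complex()
    spec = FieldSpec(
        charges=_cation_charges(mol),
        gaussians=[(25.0, np.array([2.2, 0.0, 1.5]), 0.5)],
        density_gaussians=[(1.0, np.zeros(3), 1.0)],
    )
    return Fixture("blocked_axis", mol, spec, expected_z=None)


def bump_on_monopole_fixture(q: float = 0.05, amp: float = 25.0,
                             width: float = 0.4, z_bump: float = 2.0
                             ) -> Fixture:
    """Weak monopole plus an axial Gaussian bump near ``z_bump``.

    The monopole is weak enough that the composite profile has a single
    local maximum within ``width``/10 of the bump centre.
    """
    mol = toy_complex()
    spec = FieldSpec(
        charges=[(q, np.zeros(3))],
        gaussians=[(amp, np.array([0.0, 0.0, z_bump]), width)],
        density_gaussians=[(1.0, np.zeros(3), 1.0)],
    )
    return Fixture("bump_on_monopole", mol, spec, expected_z=None)


def mirror_bump_fixture(amp: float = 25.0, width: float = 0.4,
                        z_bump: float = 2.0) -> Fixture:
    """Mirror-symmetric field with identical bumps at z = ±``z_bump``."""
    mol = toy_complex()
    spec = FieldSpec(
        charges=[(0.05, np.zeros(3))],
        gaussians=[
            (amp, np.array([0.0, 0.0, z_bump]), width),
            (amp, np.array([0.0, 0.0, -z_bump]), width),
        ],
        density_gaussians=[(1.0, np.zeros(3), 1.0)],
    )
    return Fixture("mirror_bumps", mol, spec, expected_z=None)


def anisotropic_fixture() -> Fixture:
    """Axial maximum plus an in-plane hot sector (non-zero ΔV_hole)."""
    fx = axial_depletion_fixture()
    spec = FieldSpec(
        charges=list(fx.spec.charges),
        gaussians=list(fx.spec.gaussians)
        + [(15.0, np.array([1.8, 0.0, 2.1]), 0.8)],
        density_gaussians=list(fx.spec.density_gaussians),
    )
    return Fixture("anisotropic", fx.molecule, spec, expected_z=None)


def fixture_suite() -> list[Fixture]:
    """The analytic fixtures used for property-based benchmarking."""
    return [
        axial_depletion_fixture(),
        blocked_axis_fixture(),
        bump_on_monopole_fixture(),
        mirror_bump_fixture(),
        anisotropic_fixture(),
    ]


def make_grids(fixture: Fixture,
               spacing_bohr: float = DEFAULT_GRID_SPACING_BOHR,
               padding: float = 4.0) -> tuple[ScalarGrid, ScalarGrid]:
    """(ESP, density) grids for a fixture at the requested spacing."""
    req = grid_request_for_points(fixture.molecule.coords, spacing_bohr,
                                  padding)
    spec = FieldSpec(
        charges=fixture.spec.charges,
        gaussians=fixture.spec.gaussians,
        density_gaussians=fixture.spec.density_gaussians,
        grid=req,
    )
    return point_charge_field(spec), gaussian_density(spec)
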