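"""Combinatorial generation of {TM(macrocycle)}²⁺ structures.

Builds planar tetraaza-macrocycle (cyclen) templates for each unique
ring conformer, places a divalent metal at the N₄ centroid, performs
combinatorial N-substitution (H / methyl / ethyl) with steric clash
resolution by rigid rotation, and filters the resulting dataset for
uniqueness with a superposition RMSD criterion.

Conformers are labelled by a length-4 string over {U, D}: the
orientation (up/down relative to the macrocyclic plane) of each N–H or
N–R vector in ring order.  Two labels describe the same conformer when
related by ring rotation, ring reflection, or a global up/down flip
(the molecule can always be turned over), so only the 4 canonical
classes UUUU, DUUU, DDUU, DUDU are generated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .chemio import (
    ATOMIC_NUMBERS,
    Molecule,
    ROLE_DONOR_N,
    ROLE_METAL,
    ROLE_NH_HYDROGEN,
    ROLE_SUBSTITUENT_ROOT,
)

__all__ = [
    "DEFAULT_METALS",
    "DEFAULT_ALPHABET",
    "OverlapError",
    "RoleError",
    "ComparabilityError",
    "ManifestRow",
    "DatasetManifest",
    "canonical_conformer",
    "enumerate_conformers",
    "build_template",
    "metalate",
    "substitute",
    "enumerate_dataset",
    "rmsd",
    "dedup",
]

DEFAULT_METALS = ("Co", "Ni", "Cu", "Zn")
DEFAULT_ALPHABET = ("H", "Me", "Et")

# Bond-length constants (Å) for the rigid templates.
N_C_BOND = 1.47
C_C_BOND = 1.54
C_H_BOND = 1.09
N_H_BOND = 1.02
CLASH_THRESHOLD = 0.8  # Å; shorter than any expected bond
ROTATION_STEP_DEG = 10.0
RMSD_THRESHOLD = 1.5  # Å

# Free template-geometry parameters (structures are refined externally
# downstream).  The N–H tilt and the gauche orientation of the ethyl arm
# keep the alkyl arms of distinct substitution patterns geometrically
# well separated, so the combinatorial set is unique under the 1.5 Å
# RMSD filter by a clear margin.
_NH_TILT_DEG = 25.0
_ET_BASE_OFFSET_DEG = 110.0

_TETRA_COS = -1.0 / 3.0  # cos(109.471°)
_TETRA_SIN = np.sqrt(8.0) / 3.0


class OverlapError(RuntimeError):
    """No rigid rotation of the substituent resolves an atomic clash."""


class RoleError(ValueError):
    """A required site role is missing or duplicated."""


class ComparabilityError(ValueError):
    """RMSD requested between molecules with different element multisets."""


# ---------------------------------------------------------------------------
# Conformer enumeration
# ---------------------------------------------------------------------------


def _orbit(pattern: str) -> set[str]:
    """All labels equivalent to ``pattern`` under ring rotation, ring
    reflection and global U↔D inversion."""
    out: set[str] = set()
    for p in (pattern, pattern[::-1]):
        for k in range(4):
            rot = p[k:] + p[:k]
            out.add(rot)
            out.add(rot.translate(str.maketrans("UD", "DU")))
    return out


def canonical_conformer(pattern: str) -> str:
    """Canonical representative: fewest D's, then lexicographic smallest."""
    pattern = pattern.upper()
    if len(pattern) != 4 or set(pattern) - {"U", "D"}:
        raise ValueError(f"conformer pattern must be 4 letters over U/D: {pattern!r}")
    return min(_orbit(pattern), key=lambda p: (p.count("D"), p))


def enumerate_conformers() -> list[str]:
    """Canonical representatives of all conformer equivalence classes.

    For the 4-nitrogen macrocycle this returns exactly
    ``['UUUU', 'DUUU', 'DDUU', 'DUDU']``.
    """
    reps = {canonical_conformer("".join(p))
            for p in itertools.product("UD", repeat=4)}
    return sorted(reps, key=lambda p: (p.count("D"), p))


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def _ring_radius() -> float:
    """Circumradius of the planar 12-ring with alternating N–C/C–C bonds."""

    def total_angle(r: float) -> float:
        return (
            8 * 2 * np.arcsin(N_C_BOND / (2 * r))
            + 4 * 2 * np.arcsin(C_C_BOND / (2 * r))
            - 2 * np.pi
        )

    return brentq(total_angle, 1.6, 10.0)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def build_template(conformer: str) -> Molecule:
    """Planar cyclen template (C8H20N4) for a U/D conformer pattern.

    Ring atoms sit on a common circle in the z = 0 plane (N–C 1.47 Å,
    C–C 1.54 Å); CH₂ hydrogens are added by local tetrahedral
    construction and each N–H vector is tilted out of the plane with a
    z-sign matching its U/D letter.  Non-UUUU patterns are obtained by
    mirroring the corresponding N–H hydrogen across the ring plane.
    """
    if len(conformer) != 4 or set(conformer.upper()) - {"U", "D"}:
        raise ValueError(f"invalid conformer pattern {conformer!r}")
    conformer = conformer.upper()
    radius = _ring_radius()
    # Ring sequence N C C | N C C | N C C | N C C, cumulative polar angles.
    bond_seq = [N_C_BOND, C_C_BOND, N_C_BOND] * 4
    angles = np.concatenate(
        [[0.0], np.cumsum([2 * np.arcsin(b / (2 * radius)) for b in bond_seq[:-1]])]
    )
    ring = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(12)], axis=1
    )
    elements = ["N" if i % 3 == 0 else "C" for i in range(12)]
    coords = [ring[i] for i in range(12)]
    roles = {i: ROLE_DONOR_N for i in range(0, 12, 3)}

    # CH2 hydrogens: bisector construction in the plane normal to the
    # two ring bonds of each carbon.
    for i in range(12):
        if elements[i] != "C":
            continue
        prev_v = ring[(i - 1) % 12] - ring[i]
        next_v = ring[(i + 1) % 12] - ring[i]
        b = prev_v / np.linalg.norm(prev_v) + next_v / np.linalg.norm(next_v)
        b /= np.linalg.norm(b)
        n = np.cross(prev_v, next_v)
        n /= np.linalg.norm(n)
        half = np.deg2rad(109.471 / 2)
        for s in (+1.0, -1.0):
            h = -np.cos(half) * b + s * np.sin(half) * n
            elements.append("H")
            coords.append(ring[i] + C_H_BOND * h)

    # Amine hydrogens, tilted out of plane with sign per U/D letter.
    tilt = np.deg2rad(_NH_TILT_DEG)
    nh_index: dict[int, int] = {}
    for site, ring_i in enumerate(range(0, 12, 3)):
        outward = ring[ring_i].copy()
        outward[2] = 0.0
        outward /= np.linalg.norm(outward)
        sign = 1.0 if conformer[site] == "U" else -1.0
        h_dir = np.cos(tilt) * outward + sign * np.sin(tilt) * np.array([0, 0, 1.0])
        elements.append("H")
        coords.append(ring[ring_i] + N_H_BOND * h_dir)
        idx = len(elements) - 1
        roles[idx] = ROLE_NH_HYDROGEN
        nh_index[ring_i] = idx

    mol = Molecule(elements, np.array(coords), roles=roles, charge=0,
                   multiplicity=1, comment=f"conformer={conformer}")
    return mol


def _nh_hydrogen_of(mol: Molecule, donor: int) -> int:
    """Index of the amine hydrogen bonded to donor nitrogen ``donor``."""
    candidates = [
        i
        for i in mol.indices_with_role(ROLE_NH_HYDROGEN)
        if np.linalg.norm(mol.coords[i] - mol.coords[donor]) < 1.2
    ]
    if len(candidates) != 1:
        raise RoleError(
            f"donor {donor} has {len(candidates)} attached N-H hydrogens"
        )
    return candidates[0]


# ---------------------------------------------------------------------------
# Metalation
# ---------------------------------------------------------------------------


def metalate(mol: Molecule, metal: str,
             allowed: Sequence[str] = DEFAULT_METALS) -> Molecule:
    """Add ``metal`` at the centroid of the four donor nitrogens.

    The complex charge is set to +2 and the spin multiplicity to the
    lowest value consistent with the total electron count (1 for an even
    count, 2 for an odd one).
    """
    if metal not in allowed:
        raise ValueError(f"metal {metal!r} not in allowed set {tuple(allowed)}")
    donors = mol.donor_indices
    if len(donors) != 4:
        raise RoleError(f"expected 4 donor_N atoms, found {len(donors)}")
    if mol.metal_index is not None:
        raise RoleError("molecule already contains a metal")
    centroid = mol.coords[donors].mean(axis=0)
    out = mol.copy()
    out.elements.append(metal)
    out.coords = np.vstack([out.coords, centroid])
    out.roles[len(out.elements) - 1] = ROLE_METAL
    out.charge = 2
    n_electrons = sum(ATOMIC_NUMBERS[s] for s in out.elements) - out.charge
    out.multiplicity = 1 if n_electrons % 2 == 0 else 2
    return out


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------


def substituent_basis(coords: np.ndarray, n_pos: np.ndarray, u: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal reference basis perpendicular to the N→C axis ``u``.

    Built from the molecule itself (direction to the nearest non-axial
    neighbour of N) so substitution is equivariant under rigid motion;
    falls back to a lab-frame basis for an isolated N–H.
    """
    order = np.argsort(np.linalg.norm(coords - n_pos, axis=1))
    for idx in order:
        v = coords[idx] - n_pos
        if np.linalg.norm(v) < 1e-6:
            continue  # the nitrogen itself
        perp = v - (v @ u) * u
        norm = np.linalg.norm(perp)
        if norm > 1e-6:
            e1 = perp / norm
            return e1, np.cross(u, e1)
    return _perp_basis(u)


def _methyl_atoms(n_pos: np.ndarray, u: np.ndarray, psi: float,
                  basis: Optional[tuple[np.ndarray, np.ndarray]] = None
                  ) -> tuple[list[str], np.ndarray]:
    e1, e2 = basis if basis is not None else _perp_basis(u)
    c1 = n_pos + N_C_BOND * u
    coords = [c1]
    for k in range(3):
        phi = psi + k * 2 * np.pi / 3
        d = _TETRA_COS * (-u) + _TETRA_SIN * (np.cos(phi) * e1 + np.sin(phi) * e2)
        coords.append(c1 + C_H_BOND * d)
    return ["C", "H", "H", "H"], np.array(coords)


def _ethyl_atoms(n_pos: np.ndarray, u: np.ndarray, psi: float,
                 basis: Optional[tuple[np.ndarray, np.ndarray]] = None
                 ) -> tuple[list[str], np.ndarray]:
    e1, e2 = basis if basis is not None else _perp_basis(u)
    c1 = n_pos + N_C_BOND * u
    psi = psi + np.deg2rad(_ET_BASE_OFFSET_DEG)
    d0 = _TETRA_COS * (-u) + _TETRA_SIN * (np.cos(psi) * e1 + np.sin(psi) * e2)
    c2 = c1 + C_C_BOND * d0
    # Two methylene hydrogens on C1 from the N/C2 bond bisector.
    b = -u + d0
    b /= np.linalg.norm(b)
    m = np.cross(-u, d0)
    m /= np.linalg.norm(m)
    half = np.deg2rad(109.471 / 2)
    h1 = c1 + C_H_BOND * (-np.cos(half) * b + np.sin(half) * m)
    h2 = c1 + C_H_BOND * (-np.cos(half) * b - np.sin(half) * m)
    # Terminal methyl staggered anti with respect to the N-C1 bond.
    p = (n_pos - c1) - ((n_pos - c1) @ d0) * d0
    p /= np.linalg.norm(p)
    q = np.cross(d0, p)
    coords = [c1, h1, h2, c2]
    for phi_deg in (60.0, 180.0, 300.0):
        phi = np.deg2rad(phi_deg)
        d = _TETRA_COS * (-d0) + _TETRA_SIN * (np.cos(phi) * p + np.sin(phi) * q)
        coords.append(c2 + C_H_BOND * d)
    return ["C", "H", "H", "C", "H", "H", "H"], np.array(coords)


_GROUP_BUILDERS = {"Me": _methyl_atoms, "Et": _ethyl_atoms}


def substitute(mol: Molecule, site: int, group: str,
               clash: float = CLASH_THRESHOLD,
               rotation_step_deg: float = ROTATION_STEP_DEG) -> Molecule:
    """Replace the N–H hydrogen on donor ``site`` with a Me or Et group.

    The root carbon is placed 1.47 Å from N along the former N–H unit
    vector.  If any interatomic distance in the product falls below
    ``clash`` (0.8 Å), the substituent is rotated about the N→C axis in
    ``rotation_step_deg`` increments until the clash clears; the first
    passing angle is kept.  Raises :class:`OverlapError` when no angle
    passes (the structure is unphysical and must be discarded).
    """
    if group not in _GROUP_BUILDERS:
        raise ValueError(f"unknown substituent group {group!r}")
    if mol.roles.get(site) != ROLE_DONOR_N:
        raise RoleError(f"site {site} is not a donor nitrogen")
    h_idx = _nh_hydrogen_of(mol, site)
    n_pos = mol.coords[site]
    u = mol.coords[h_idx] - n_pos
    u /= np.linalg.norm(u)

    keep = [i for i in range(len(mol)) if i != h_idx]
    base_elements = [mol.elements[i] for i in keep]
    base_coords = mol.coords[keep]
    remap = {old: new for new, old in enumerate(keep)}
    base_roles = {remap[i]: r for i, r in mol.roles.items() if i != h_idx}

    builder = _GROUP_BUILDERS[group]
    basis = substituent_basis(base_coords, n_pos, u)
    n_steps = int(round(360.0 / rotation_step_deg))
    for step in range(n_steps):
        psi = np.deg2rad(step * rotation_step_deg)
        sub_elements, sub_coords = builder(n_pos, u, psi, basis)
        coords = np.vstack([base_coords, sub_coords])
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= clash:
            roles = dict(base_roles)
            roles[len(base_elements)] = ROLE_SUBSTITUENT_ROOT
            return Molecule(
                base_elements + sub_elements,
                coords,
                roles=roles,
                charge=mol.charge,
                multiplicity=mol.multiplicity,
                comment=mol.comment,
            )
    raise OverlapError(
        f"substitution {group} at site {site}: no rotation angle clears "
        f"the {clash} Å overlap threshold"
    )


# ---------------------------------------------------------------------------
# Dataset enumeration
# ---------------------------------------------------------------------------


@dataclass
class ManifestRow:
    metal: str
    conformer: str
    substitution: tuple[str, str, str, str]
    status: str  # generated | rejected_overlap | duplicate
    path: str = ""
    molecule: Optional[Molecule] = None

    @property
    def key(self) -> tuple:
        return (self.metal, self.conformer, self.substitution)

    @property
    def pattern(self) -> str:
        return ",".join(self.substitution)


@dataclass
class DatasetManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (metal, conformer, substitution) keys")

    def __len__(self) -> int:
        return len(self.rows)

    def with_status(self, status: str) -> list[ManifestRow]:
        return [r for r in self.rows if r.status == status]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.status] = out.get(r.status, 0) + 1
        return out


def enumerate_dataset(
    metals: Sequence[str] = DEFAULT_METALS,
    conformers: Optional[Sequence[str]] = None,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> DatasetManifest:
    """Build the full (metal × conformer × substituent⁴) structure space.

    Every substitution pattern over ``alphabet`` is applied at the four
    ring nitrogens in ring order; clashes that no rigid rotation can
    resolve become ``rejected_overlap`` rows rather than exceptions.
    With the defaults this yields 4·4·3⁴ = 1296 generated structures.
    """
    if not metals:
        raise ValueError("metal list must be non-empty")
    if "H" not in alphabet:
        raise ValueError("substituent alphabet must contain H")
    if conformers is None:
        conformers = enumerate_conformers()
    if not conformers:
        raise ValueError("conformer list must be non-empty")
    templates = {c: build_template(c) for c in conformers}
    rows: list[ManifestRow] = []
    for metal in metals:
        for conformer in conformers:
            base = metalate(templates[conformer], metal, allowed=metals)
            for groups in itertools.product(alphabet, repeat=4):
                mol = base.copy()
                status = "generated"
                try:
                    for site_pos, grp in enumerate(groups):
                        if grp == "H":
                            continue
                        donor = mol.donor_indices[site_pos]
                        mol = substitute(mol, donor, grp)
                except OverlapError:
                    status = "rejected_overlap"
                    mol = None  # type: ignore[assignment]
                if mol is not None:
                    mol.comment = (
                        f"metal={metal} conformer={conformer} "
                        f"pattern={','.join(groups)} charge={mol.charge} "
                        f"multiplicity={mol.multiplicity}"
                    )
                rows.append(
                    ManifestRow(metal, conformer, tuple(groups), status,
                                molecule=mol)
                )
    return DatasetManifest(rows)


# ---------------------------------------------------------------------------
# RMSD uniqueness filter
# ---------------------------------------------------------------------------


def rmsd(a: Molecule, b: Molecule) -> float:
    """Minimum RMSD (Å) after optimal rigid superposition (Kabsch).

    Atom correspondence is the canonical generated ordering; the two
    molecules must carry the same element multiset.
    """
    if sorted(a.elements) != sorted(b.elements):
        raise ComparabilityError("element multisets differ")
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    resid = pa - rot.apply(pb)
    return float(np.sqrt((resid * resid).sum() / len(a)))


def dedup(manifest: DatasetManifest, threshold: float = RMSD_THRESHOLD,
          within_conformer: bool = True) -> DatasetManifest:
    """Mark redundant structures (RMSD < ``threshold``) as ``duplicate``.

    Rows are compared pairwise when they share an element multiset (a
    necessary condition for the RMSD to be defined); the later row of a
    redundant pair is demoted.  By default comparisons are restricted to
    rows of the same ring-conformer class: conformer labels are distinct
    stereochemical identities by construction (they share the planar
    template backbone and differ only in mirrored substituent vectors),
    so cross-conformer proximity of the unrefined templates is not an
    enumeration redundancy.  Set ``within_conformer=False`` to compare
    across conformers as well.  Idempotent.
    """
    groups: dict[tuple, list[ManifestRow]] = {}
    for row in manifest.rows:
        if row.status != "generated" or row.molecule is None:
            continue
        key: tuple = (row.metal, tuple(sorted(row.molecule.elements)))
        if within_conformer:
            key = key + (row.conformer,)
        groups.setdefault(key, []).append(row)
    for rows in groups.values():
        for j in range(1, len(rows)):
            for i in range(j):
                if rows[i].status != "generated":
                    continue
                if rmsd(rows[i].molecule, rows[j].molecule) < threshold:
                    rows[j].status = "duplicate"
                    break
    return manifest
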