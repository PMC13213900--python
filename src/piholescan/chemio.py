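"""Molecular and volumetric-grid containers plus XYZ / Gaussian-cube I/O.

All coordinates handed to the rest of the package are in Å; ESP grids
are in kcal mol⁻¹ e⁻¹ and density grids in e bohr⁻³.  Cube files store
lengths in bohr and ESP in hartree e⁻¹; the readers/writers convert.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL

__all__ = [
    "Molecule",
    "ScalarGrid",
    "ParseError",
    "FormatError",
    "read_xyz",
    "write_xyz",
    "read_cube",
    "write_cube",
]

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu"
).split()
ATOMIC_NUMBERS = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
SYMBOLS = {v: k for k, v in ATOMIC_NUMBERS.items()}

# Role tags recognised on Molecule.roles values.
ROLE_DONOR_N = "donor_N"
ROLE_METAL = "metal"
ROLE_NH_HYDROGEN = "NH_hydrogen"
ROLE_SUBSTITUENT_ROOT = "substituent_root"


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed; carries line info."""


class FormatError(ValueError):
    """Raised when a volumetric file violates the supported dialect."""


@dataclass
class Molecule:
    """Element symbols + Cartesian coordinates (Å) with optional site roles.

    ``roles`` maps atom index -> role tag (``donor_N``, ``metal``,
    ``NH_hydrogen``, ``substituent_root``).  ``charge`` is the total
    charge in e; ``multiplicity`` the spin multiplicity 2S+1.
    """

    elements: list[str]
    coords: np.ndarray
    roles: dict[int, str] = field(default_factory=dict)
    charge: int = 0
    multiplicity: int = 1
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if len(self.elements) < 1:
            raise ValueError("molecule needs at least one atom")
        for sym in self.elements:
            if sym not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {sym!r}")
        for idx in self.roles:
            if not 0 <= idx < len(self.elements):
                raise ValueError(f"role index {idx} out of range")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("molecule contains exactly coincident atoms")

    def __len__(self) -> int:
        return len(self.elements)

    def indices_with_role(self, role: str) -> list[int]:
        return sorted(i for i, r in self.roles.items() if r == role)

    @property
    def donor_indices(self) -> list[int]:
        return self.indices_with_role(ROLE_DONOR_N)

    @property
    def metal_index(self) -> Optional[int]:
        idx = self.indices_with_role(ROLE_METAL)
        if len(idx) > 1:
            raise ValueError("more than one atom tagged metal")
        return idx[0] if idx else None

    def min_pair_distance(self) -> float:
        """Smallest interatomic distance (Å) over all atom pairs."""
        d = self.coords[:, None, :] - self.coords[None, :, :]
        r = np.sqrt((d * d).sum(axis=-1))
        n = len(self)
        return float(r[np.triu_indices(n, k=1)].min()) if n > 1 else np.inf

    def copy(self) -> "Molecule":
        return Molecule(
            list(self.elements),
            self.coords.copy(),
            dict(self.roles),
            self.charge,
            self.multiplicity,
            self.comment,
        )


@dataclass
class ScalarGrid:
    """Uniform rectilinear 3D scalar field.

    ``origin`` (Å) is the position of voxel (0,0,0); ``axes`` is a 3x3
    matrix whose *rows* are the per-index spacing vectors (Å); ``values``
    has shape ``shape`` and is indexed values[i, j, k] for the point
    origin + i*axes[0] + j*axes[1] + k*axes[2].  ``kind`` tags the units:
    ``esp_kcalmol`` or ``density_au``.
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    kind: str = "esp_kcalmol"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.kind not in ("esp_kcalmol", "density_au"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        norms = np.linalg.norm(self.axes, axis=1)
        if np.any(norms <= 0):
            raise FormatError("zero-length grid axis")
        dots = self.axes @ self.axes.T
        off = dots - np.diag(np.diag(dots))
        if np.max(np.abs(off)) > 1e-8 * float(np.max(norms)) ** 2:
            raise FormatError("grid axes are not orthogonal")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis step lengths (Å)."""
        return np.linalg.norm(self.axes, axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) of the voxel-node bounding box (Å)."""
        corners = []
        n = np.asarray(self.shape) - 1
        for ix in (0, n[0]):
            for iy in (0, n[1]):
                for iz in (0, n[2]):
                    corners.append(
                        self.origin
                        + ix * self.axes[0]
                        + iy * self.axes[1]
                        + iz * self.axes[2]
                    )
        c = np.array(corners)
        return c.min(axis=0), c.max(axis=0)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"(\w+)=(\S+)")


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment, element x y z in Å).

    The comment line is preserved; ``key=value`` tokens in it are parsed
    into ``Molecule`` metadata when the keys are recognised (charge,
    multiplicity) and kept verbatim otherwise.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (line 1)")
    try:
        natoms = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path}: malformed atom-count line (line 1)") from None
    if natoms < 1:
        raise ParseError(f"{path}: atom count must be positive (line 1)")
    comment = lines[1] if len(lines) > 1 else ""
    records = lines[2 : 2 + natoms]
    if len(records) < natoms:
        raise ParseError(
            f"{path}: count line says {natoms} atoms but only "
            f"{len(records)} records present (line {2 + len(records)})"
        )
    elements: list[str] = []
    coords = np.empty((natoms, 3))
    for i, line in enumerate(records):
        parts = line.split()
        lineno = i + 3
        if len(parts) < 4:
            raise ParseError(f"{path}: truncated atom record (line {lineno})")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise ParseError(
                f"{path}: unknown element symbol {parts[0]!r} (line {lineno})"
            )
        try:
            coords[i] = [float(x) for x in parts[1:4]]
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric coordinate (line {lineno})"
            ) from None
        elements.append(sym)
    meta = dict(_META_RE.findall(comment))
    charge = int(meta.get("charge", 0))
    multiplicity = int(meta.get("multiplicity", 1))
    return Molecule(elements, coords, charge=charge, multiplicity=multiplicity,
                    comment=comment)


def write_xyz(mol: Molecule, path, comment: Optional[str] = None) -> None:
    """Write ``mol`` as a standard XYZ file (coordinates in Å)."""
    text = comment if comment is not None else mol.comment
    text = (text or "").replace("\n", " ")
    with open(path, "w") as fh:
        fh.write(f"{len(mol)}\n{text}\n")
        for sym, (x, y, z) in zip(mol.elements, mol.coords):
            fh.write(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------


def read_cube(path, kind: str = "esp_kcalmol", values_in_hartree: bool = True
              ) -> tuple[ScalarGrid, Molecule]:
    """Read a Gaussian cube file into a :class:`ScalarGrid` plus atoms.

    Lengths are converted bohr→Å.  For ``kind='esp_kcalmol'`` the voxel
    values are converted hartree·e⁻¹ → kcal mol⁻¹ e⁻¹ unless
    ``values_in_hartree=False`` (for cubes already written in kcal/mol).
    Density cubes (``kind='density_au'``) keep native e bohr⁻³.

    Only scalar-field cubes are supported: a negative atom count (the
    molecular-orbital cube convention) is rejected.
    """
    with open(path) as fh:
        lines = fh.read().split("\n")
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated cube header")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin_bohr = np.array([float(x) for x in head[1:4]])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed cube origin record") from None
    if natoms < 0:
        raise FormatError(
            f"{path}: negative atom count (MO cube dialect) is not supported"
        )
    counts = np.empty(3, dtype=int)
    axes_bohr = np.empty((3, 3))
    for ax in range(3):
        parts = lines[3 + ax].split()
        try:
            counts[ax] = int(parts[0])
            axes_bohr[ax] = [float(x) for x in parts[1:4]]
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed cube axis record {ax}") from None
        if counts[ax] <= 0:
            raise FormatError(f"{path}: non-positive voxel count on axis {ax}")
    elements: list[str] = []
    coords_bohr = np.empty((natoms, 3))
    for i in range(natoms):
        parts = lines[6 + i].split()
        try:
            z = int(parts[0])
            coords_bohr[i] = [float(x) for x in parts[2:5]]
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed cube atom record {i}") from None
        if z not in SYMBOLS:
            raise FormatError(f"{path}: unknown atomic number {z}")
        elements.append(SYMBOLS[z])
    raw = " ".join(lines[6 + natoms:]).split()
    nval = int(np.prod(counts))
    if len(raw) < nval:
        raise FormatError(
            f"{path}: truncated value stream ({len(raw)} of {nval} values)"
        )
    values = np.array(raw[:nval], dtype=float).reshape(tuple(counts))
    if kind == "esp_kcalmol" and values_in_hartree:
        values = values * HARTREE_TO_KCALMOL
    grid = ScalarGrid(
        origin=origin_bohr * BOHR_TO_ANGSTROM,
        axes=axes_bohr * BOHR_TO_ANGSTROM,
        values=values,
        kind=kind,
    )
    if natoms:
        mol = Molecule(elements, coords_bohr * BOHR_TO_ANGSTROM)
    else:
        mol = Molecule(["H"], np.zeros((1, 3)))  # placeholder for atomless cubes
    return grid, mol


def write_cube(grid: ScalarGrid, mol: Optional[Molecule], path,
               comment: str = "piholescan scalar field") -> None:
    """Write a Gaussian cube (bohr; ESP values back-converted to hartree)."""
    values = grid.values
    if grid.kind == "esp_kcalmol":
        values = values / HARTREE_TO_KCALMOL
    origin_bohr = grid.origin * ANGSTROM_TO_BOHR
    axes_bohr = grid.axes * ANGSTROM_TO_BOHR
    natoms = len(mol) if mol is not None else 0
    with open(path, "w") as fh:
        fh.write(f"{comment}\n{grid.kind}\n")
        fh.write(
            f"{natoms:5d} {origin_bohr[0]:19.12f} {origin_bohr[1]:19.12f} "
            f"{origin_bohr[2]:19.12f}\n"
        )
        for ax in range(3):
            v = axes_bohr[ax]
            fh.write(
                f"{grid.shape[ax]:5d} {v[0]:19.12f} {v[1]:19.12f} {v[2]:19.12f}\n"
            )
        if mol is not None:
            for sym, pos in zip(mol.elements, mol.coords * ANGSTROM_TO_BOHR):
                z = ATOMIC_NUMBERS[sym]
                fh.write(
                    f"{z:5d} {float(z):11.6f} {pos[0]:19.12f} {pos[1]:19.12f} "
                    f"{pos[2]:19.12f}\n"
                )
        flat = values.reshape(-1)
        for start in range(0, len(flat), 6):
            chunk = flat[start : start + 6]
            fh.write(" ".join(f"{x: .11E}" for x in chunk) + "\n")
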