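"""Aligned molecular reference frame and four-coordinate geometry descriptors.

The four donor nitrogens of the macrocycle define the N₄-plane.  Its
least-squares normal n̂ is the molecular pseudo-z axis (π-axis); the
in-plane x-axis follows the shortest N–N difference vector so that all
complexes share a consistent orientation.  Points map into the aligned
frame via  r_aligned = (r_original − r_centroid) · Rot.

τ₄ quantifies the distortion of a four-coordinate metal site along the
square-planar → tetrahedral path:  τ₄ = [360° − (α + β)] / 141°, with
α ≥ β the two largest donor–metal–donor angles.  τ₄ = 0 for an ideal
square plane (α = β = 180°) and 1 for an ideal tetrahedron.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .chemio import Molecule
from .structgen import RoleError

__all__ = [
    "Frame",
    "GeometryDescriptors",
    "FitError",
    "fit_plane",
    "align",
    "unalign",
    "tau4",
    "geometry_descriptors",
]

TAU4_DENOMINATOR_DEG = 141.0


class FitError(ValueError):
    """Degenerate point set: no well-defined best-fit plane."""


@dataclass
class Frame:
    """Affine map into the aligned π-axis frame.

    ``rotation`` has the aligned-frame basis vectors as *columns*
    (x̂, ŷ, n̂), so aligned coordinates are ``(r - centroid) @ rotation``.
    """

    centroid: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @property
    def normal(self) -> np.ndarray:
        """Unit π-axis n̂ in lab coordinates (third basis column)."""
        return self.rotation[:, 2]

    def flipped(self) -> "Frame":
        """Frame with the π-axis reversed (x kept, y and n negated)."""
        rot = self.rotation * np.array([1.0, -1.0, -1.0])
        return Frame(self.centroid, rot)


def fit_plane(nitrogens: np.ndarray) -> Frame:
    """Best-fit plane frame through four donor-nitrogen positions.

    The centroid is the arithmetic mean; the normal is the direction of
    smallest variance of the centred points (SVD).  The in-plane x-axis
    is the projection of the shortest N–N difference vector (lowest
    donor-index pair on ties); y completes a right-handed triad.  The
    normal's sign is fixed deterministically (largest-magnitude lab
    component positive); callers that care about hemispheres analyse
    both signs.
    """
    pts = np.asarray(nitrogens, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("fit_plane expects four 3-vectors")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-10:
        raise FitError("nitrogen positions are collinear or coincident")
    normal = vt[2]
    # Deterministic sign: make the dominant lab component positive.
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    # Shortest N-N difference vector, projected into the plane.
    pairs = sorted(
        combinations(range(4), 2),
        key=lambda ij: (np.linalg.norm(pts[ij[1]] - pts[ij[0]]), ij),
    )
    x_axis = None
    for i, j in pairs:
        v = pts[j] - pts[i]
        v = v - (v @ normal) * normal
        if np.linalg.norm(v) > 1e-10:
            x_axis = v / np.linalg.norm(v)
            break
    if x_axis is None:
        raise FitError("no in-plane N-N direction found")
    y_axis = np.cross(normal, x_axis)
    rotation = np.stack([x_axis, y_axis, normal], axis=1)
    return Frame(centroid, rotation)


def align(points: np.ndarray, frame: Frame) -> np.ndarray:
    """Map lab-frame points into the aligned frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = (pts - frame.centroid) @ frame.rotation
    return out.reshape(np.shape(points))


def unalign(points: np.ndarray, frame: Frame) -> np.ndarray:
    """Inverse of :func:`align`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ frame.rotation.T + frame.centroid
    return out.reshape(np.shape(points))


def tau4(metal: np.ndarray, donors: np.ndarray) -> float:
    """Four-coordinate geometry index from the two largest L–M–L angles."""
    alpha, beta = _two_largest_angles(metal, donors)
    return (360.0 - (alpha + beta)) / TAU4_DENOMINATOR_DEG


def _two_largest_angles(metal: np.ndarray, donors: np.ndarray
                        ) -> tuple[float, float]:
    metal = np.asarray(metal, dtype=float).reshape(3)
    donors = np.asarray(donors, dtype=float).reshape(4, 3)
    vecs = donors - metal
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-10):
        raise ValueError("zero-length metal-donor vector")
    unit = vecs / norms[:, None]
    angles = []
    for i, j in combinations(range(4), 2):
        c = np.clip(unit[i] @ unit[j], -1.0, 1.0)
        angles.append(np.degrees(np.arccos(c)))
    angles.sort(reverse=True)
    return angles[0], angles[1]


@dataclass
class GeometryDescriptors:
    tau4: float
    mn_distances: np.ndarray  # four M-N distances, Å, donor order
    mn_mean: float
    alpha: float  # largest N-M-N angle, degrees
    beta: float   # second-largest N-M-N angle, degrees


def geometry_descriptors(mol: Molecule) -> GeometryDescriptors:
    """τ₄, M–N distances and the two largest N–M–N angles of a complex."""
    donors = mol.donor_indices
    metal_idx = mol.metal_index
    if len(donors) != 4 or metal_idx is None:
        raise RoleError("molecule needs 4 donor_N atoms and one metal")
    m = mol.coords[metal_idx]
    d = mol.coords[donors]
    alpha, beta = _two_largest_angles(m, d)
    dists = np.linalg.norm(d - m, axis=1)
    return GeometryDescriptors(
        tau4=(360.0 - (alpha + beta)) / TAU4_DENOMINATOR_DEG,
        mn_distances=dists,
        mn_mean=float(dists.mean()),
        alpha=alpha,
        beta=beta,
    )
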