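"""Synthetic volumetric fields, trilinear sampling and isosurface V_s,max.

The generators build analytic stand-ins for QM-derived cube data:
point-charge Coulomb ESPs (V = 332.0637 Σ qᵢ/rᵢ in kcal mol⁻¹ e⁻¹),
Gaussian ESP features, and model Gaussian electron densities.  They are
fully deterministic given a :class:`FieldSpec`.

V_s,max is the maximum ESP over the ρ = 0.001 e bohr⁻³ isodensity
surface; the surface is the marching-cubes vertex set (linear edge
crossings), because evaluating on raw voxel masks shifts values by
O(grid spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.measure import marching_cubes

from .chemio import ScalarGrid
from .constants import (
    BOHR_TO_ANGSTROM,
    COULOMB_K,
    DEFAULT_GRID_PADDING_ANGSTROM,
    DEFAULT_GRID_SPACING_BOHR,
    DEFAULT_ISO_DENSITY,
)

__all__ = [
    "FieldSpec",
    "GridRequest",
    "SamplingError",
    "EmptySurfaceError",
    "CoverageError",
    "sample",
    "point_charge_field",
    "gaussian_esp_field",
    "gaussian_density",
    "isosurface_points",
    "vs_max",
    "grid_request_for_points",
]

# Distance (Å) below which the Coulomb potential is clamped to avoid
# singular voxels; only affects regions no detector ever samples.
NEAR_CHARGE_CLAMP = 0.1


class SamplingError(ValueError):
    """A query point lies outside the grid bounding box."""

    def __init__(self, point):
        self.point = np.asarray(point)
        super().__init__(f"point {self.point} outside grid bounds")


class EmptySurfaceError(ValueError):
    """The iso value is outside the grid's value range."""


class CoverageError(ValueError):
    """Too many required sample points fall outside the grid."""


@dataclass
class GridRequest:
    """Axis-aligned uniform grid request: origin (Å), shape, spacing (Å)."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if any(s < 2 for s in self.shape):
            raise ValueError("grid shape must be >= 2 per axis")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def axes(self) -> np.ndarray:
        return np.eye(3) * self.spacing

    def node_coordinates(self) -> np.ndarray:
        """All node positions, shape (nx, ny, nz, 3)."""
        ii = [self.origin[k] + self.spacing * np.arange(self.shape[k])
              for k in range(3)]
        gx, gy, gz = np.meshgrid(*ii, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class FieldSpec:
    """Analytic field recipe: Coulomb charges + Gaussian ESP/density terms.

    ``charges``: (q [e], position [Å]) pairs.
    ``gaussians``: ESP features (amplitude [kcal/mol], center [Å], width [Å]).
    ``density_gaussians``: (amplitude [e bohr⁻³], center [Å], width [bohr]).
    """

    charges: list[tuple[float, np.ndarray]] = field(default_factory=list)
    gaussians: list[tuple[float, np.ndarray, float]] = field(default_factory=list)
    density_gaussians: list[tuple[float, np.ndarray, float]] = field(
        default_factory=list)
    grid: Optional[GridRequest] = None

    def __post_init__(self) -> None:
        for amp, c, w in self.gaussians + self.density_gaussians:
            if w <= 0:
                raise ValueError("gaussian widths must be positive")

    def esp_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic ESP (kcal mol⁻¹ e⁻¹) at arbitrary points, clamped
        within NEAR_CHARGE_CLAMP of any point charge."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts))
        for q, pos in self.charges:
            r = np.linalg.norm(pts - np.asarray(pos), axis=1)
            r = np.maximum(r, NEAR_CHARGE_CLAMP)
            out += COULOMB_K * q / r
        for amp, c, w in self.gaussians:
            r2 = ((pts - np.asarray(c)) ** 2).sum(axis=1)
            out += amp * np.exp(-r2 / (2.0 * w * w))
        return out if np.ndim(points) == 2 else out  # always 1-D

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic model density (e bohr⁻³) at arbitrary points (Å)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts))
        for amp, c, w_bohr in self.density_gaussians:
            w = w_bohr * BOHR_TO_ANGSTROM
            r2 = ((pts - np.asarray(c)) ** 2).sum(axis=1)
            out += amp * np.exp(-r2 / (2.0 * w * w))
        return out

    def rotated(self, rotation: np.ndarray, translation=np.zeros(3)) -> "FieldSpec":
        """Spec under the rigid motion r -> r @ Rᵀ + t (grid not carried)."""
        R = np.asarray(rotation)
        t = np.asarray(translation, dtype=float)
        return FieldSpec(
            charges=[(q, np.asarray(p) @ R.T + t) for q, p in self.charges],
            gaussians=[(a, np.asarray(c) @ R.T + t, w)
                       for a, c, w in self.gaussians],
            density_gaussians=[(a, np.asarray(c) @ R.T + t, w)
                               for a, c, w in self.density_gaussians],
        )


def grid_request_for_points(
    points: np.ndarray,
    spacing_bohr: float = DEFAULT_GRID_SPACING_BOHR,
    padding: float = DEFAULT_GRID_PADDING_ANGSTROM,
) -> GridRequest:
    """Axis-aligned grid covering ``points`` with symmetric padding.

    The origin is anchored to the point set's bounding box (not to any
    absolute lattice), so translating the points translates the grid
    nodes identically.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    spacing = spacing_bohr * BOHR_TO_ANGSTROM
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return GridRequest(origin=lo, shape=shape, spacing=spacing)


def _evaluate_on_grid(spec: FieldSpec, kind: str) -> ScalarGrid:
    if spec.grid is None:
        raise ValueError("FieldSpec carries no grid request")
    nodes = spec.grid.node_coordinates()
    flat = nodes.reshape(-1, 3)
    if kind == "esp_kcalmol":
        vals = spec.esp_at(flat)
    else:
        vals = spec.density_at(flat)
    return ScalarGrid(
        origin=spec.grid.origin,
        axes=spec.grid.axes(),
        values=vals.reshape(nodes.shape[:3]),
        kind=kind,
    )


def point_charge_field(spec: FieldSpec) -> ScalarGrid:
    """ESP grid of the spec's Coulomb charges + Gaussian ESP features."""
    return _evaluate_on_grid(spec, "esp_kcalmol")


def gaussian_density(spec: FieldSpec) -> ScalarGrid:
    """Model electron-density grid (e bohr⁻³) of the density Gaussians."""
    return _evaluate_on_grid(spec, "density_au")


gaussian_esp_field = point_charge_field  # same evaluator; alias for clarity


# ---------------------------------------------------------------------------
# Trilinear sampling
# ---------------------------------------------------------------------------


def sample(grid: ScalarGrid, points: np.ndarray,
           allow_outside: bool = False) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at one or many points (Å).

    Exact at voxel nodes and on fields linear in the coordinates.
    Out-of-bounds queries raise :class:`SamplingError` unless
    ``allow_outside`` is set, in which case they return NaN.
    """
    single = np.ndim(points) == 1
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # Fractional index coordinates: solve (p - origin) = f @ axes.
    frac = (pts - grid.origin) @ np.linalg.inv(grid.axes)
    shape = np.asarray(grid.shape)
    eps = 1e-9
    inside = np.all((frac >= -eps) & (frac <= shape - 1 + eps), axis=1)
    if not allow_outside and not np.all(inside):
        bad = pts[~inside][0]
        raise SamplingError(bad)
    frac = np.clip(frac, 0.0, shape - 1)
    i0 = np.minimum(frac.astype(int), shape - 2)
    t = frac - i0
    v = np.zeros(len(pts))
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                v += (wx * wy * wz) * grid.values[
                    i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                ]
    v = np.where(inside, v, np.nan)
    return float(v[0]) if single else v


# ---------------------------------------------------------------------------
# Isosurface extraction and V_s,max
# ---------------------------------------------------------------------------


def isosurface_points(density: ScalarGrid,
                      iso: float = DEFAULT_ISO_DENSITY) -> np.ndarray:
    """Vertex set of the ``iso`` e bohr⁻³ isodensity surface (Å).

    Marching-cubes vertices are linear interpolations along grid edges
    whose node values bracket ``iso``, so every returned point carries
    an interpolated density within a few percent of ``iso``.
    """
    vmin, vmax = float(density.values.min()), float(density.values.max())
    if not (vmin < iso < vmax):
        raise EmptySurfaceError(
            f"iso {iso} outside grid value range [{vmin:.3g}, {vmax:.3g}]"
        )
    verts, _, _, _ = marching_cubes(density.values, level=iso)
    return density.origin + verts @ density.axes


def vs_max(esp: ScalarGrid, surface: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum ESP over a surface point set, with its location.

    Surface points outside the ESP grid are skipped; more than 1%
    unsampleable points raises :class:`CoverageError`.
    """
    surface = np.atleast_2d(np.asarray(surface, dtype=float))
    if len(surface) == 0:
        raise EmptySurfaceError("empty surface point set")
    vals = sample(esp, surface, allow_outside=True)
    bad = np.isnan(vals)
    if bad.mean() > 0.01:
        raise CoverageError(
            f"{bad.sum()} of {len(vals)} surface points outside the ESP grid"
        )
    vals = np.where(bad, -np.inf, vals)
    k = int(np.argmax(vals))
    return float(vals[k]), surface[k]
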