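"""Batch orchestration: dataset generation, analysis, sensitivity, reports.

The functions here are the library faces of the CLI subcommands; they
work on paths and pandas DataFrames and never require the CLI itself.
All CSV outputs carry a versioned schema header comment and are fully
deterministic for a given configuration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import structgen
from .chemio import Molecule, ScalarGrid, read_cube, read_xyz, write_cube, write_xyz
from .constants import DEFAULT_GRID_SPACING_BOHR, DEFAULT_ISO_DENSITY
from .espfield import FieldSpec, grid_request_for_points, point_charge_field, \
    gaussian_density
from .fixtures import Fixture, fixture_suite, make_grids
from .frame import geometry_descriptors
from .pihole import DetectionParams, analyze_complex

__all__ = [
    "RunConfig",
    "MANIFEST_SCHEMA",
    "DESCRIPTOR_SCHEMA",
    "infer_roles",
    "cmd_generate",
    "cmd_synth_esp",
    "cmd_analyze",
    "cmd_grid_sensitivity",
    "cmd_report",
]

log = logging.getLogger("piholescan")

MANIFEST_SCHEMA = "# piholescan manifest schema v1"
DESCRIPTOR_SCHEMA = "# piholescan descriptors schema v1"
REPORT_SCHEMA = "# piholescan report schema v1"

DESCRIPTOR_COLUMNS = [
    "name", "metal", "conformer", "pattern", "hemisphere", "status", "valid",
    "z", "V_candidate", "Vs_max", "V_hole_mean", "V_hole_max", "V_hole_min",
    "dV_hole", "dV_angle", "tau4", "mn_mean", "alpha", "beta",
]


class EmptyRunError(RuntimeError):
    """No input pair could be analyzed."""


@dataclass
class RunConfig:
    """Registry of every tunable constant of the workflow."""

    metals: tuple[str, ...] = structgen.DEFAULT_METALS
    conformers: Optional[tuple[str, ...]] = None  # None -> enumerate
    alphabet: tuple[str, ...] = structgen.DEFAULT_ALPHABET
    # structure generation
    nc_dist: float = structgen.N_C_BOND
    clash: float = structgen.CLASH_THRESHOLD
    rot_step: float = structgen.ROTATION_STEP_DEG
    rmsd_thr: float = structgen.RMSD_THRESHOLD
    # detection
    zmax: float = 3.0
    cand_radius: float = 1.0
    axial_step: float = 0.05
    sector_radius: float = 2.5
    sector_halfheight: float = 0.25
    n_sectors: int = 8
    n_samples: int = 1000
    thr: float = 5.0
    sampler: str = "stratified"
    # grids
    grid_spacing_bohr: float = DEFAULT_GRID_SPACING_BOHR
    grid_padding: float = 4.0
    iso_density: float = DEFAULT_ISO_DENSITY
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.metals:
            raise ValueError("metal list must be non-empty")
        if self.conformers is not None and not self.conformers:
            raise ValueError("conformer list must be non-empty")
        if not self.alphabet:
            raise ValueError("substituent alphabet must be non-empty")
        if self.thr < 0:
            raise ValueError("thr must be >= 0")

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            zmax=self.zmax, radius=self.cand_radius, step=self.axial_step,
            sector_radius=self.sector_radius,
            sector_halfheight=self.sector_halfheight,
            n_sectors=self.n_sectors, n_samples=self.n_samples,
            thr=self.thr, sampler=self.sampler, seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("metals", "conformers", "alphabet"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def infer_roles(mol: Molecule, metals: Sequence[str] = structgen.DEFAULT_METALS
                ) -> Molecule:
    """Tag donor nitrogens and the metal on a role-less molecule.

    All N atoms are taken as donors (there must be exactly four) and
    the single atom whose element is in ``metals`` as the metal.
    """
    out = mol.copy()
    n_idx = [i for i, s in enumerate(out.elements) if s == "N"]
    m_idx = [i for i, s in enumerate(out.elements) if s in metals]
    if len(n_idx) != 4:
        raise structgen.RoleError(f"expected 4 nitrogens, found {len(n_idx)}")
    if len(m_idx) != 1:
        raise structgen.RoleError(f"expected 1 metal atom, found {len(m_idx)}")
    for i in n_idx:
        out.roles[i] = "donor_N"
    out.roles[m_idx[0]] = "metal"
    return out


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------


def cmd_generate(config: RunConfig, outdir) -> pd.DataFrame:
    """Enumerate, deduplicate and write the structure dataset.

    Writes one XYZ per generated structure plus ``manifest.csv`` and
    returns the manifest as a DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conformers = config.conformers or structgen.enumerate_conformers()
    manifest = structgen.enumerate_dataset(config.metals, conformers,
                                           config.alphabet)
    structgen.dedup(manifest, config.rmsd_thr)
    records = []
    for row in manifest.rows:
        path = ""
        if row.status == "generated" and row.molecule is not None:
            fname = f"{row.metal}_{row.conformer}_{'-'.join(row.substitution)}.xyz"
            write_xyz(row.molecule, outdir / fname)
            path = fname
        records.append(
            {"metal": row.metal, "conformer": row.conformer,
             "pattern": row.pattern, "status": row.status, "path": path}
        )
    df = pd.DataFrame.from_records(records)
    _write_csv(df, outdir / "manifest.csv", MANIFEST_SCHEMA)
    for status, n in sorted(manifest.counts().items()):
        log.info("generate: %d rows with status %s", n, status)
    return df


# ---------------------------------------------------------------------------
# synth-esp
# ---------------------------------------------------------------------------


def synthetic_spec_for(mol: Molecule, metal_q: float = 2.0,
                       donor_q: float = -0.4,
                       axial_bump: Optional[tuple[float, float, float]] = None
                       ) -> FieldSpec:
    """Point-charge + model-density spec for a tagged complex.

    ``axial_bump`` = (amplitude kcal/mol, z-offset Å, width Å) adds a
    positive ESP Gaussian on the +z axis above the donor centroid.
    """
    donors = mol.donor_indices
    metal = mol.metal_index
    if len(donors) != 4 or metal is None:
        raise structgen.RoleError("synthetic spec needs 4 donors and a metal")
    charges = [(donor_q, mol.coords[i].copy()) for i in donors]
    charges.append((metal_q, mol.coords[metal].copy()))
    gaussians = []
    if axial_bump is not None:
        amp, dz, width = axial_bump
        centroid = mol.coords[donors].mean(axis=0)
        gaussians.append((amp, centroid + np.array([0.0, 0.0, dz]), width))
    density_gaussians = [(0.05, mol.coords[i].copy(), 1.5)
                         for i in range(len(mol))]
    return FieldSpec(charges=charges, gaussians=gaussians,
                     density_gaussians=density_gaussians)


def cmd_synth_esp(config: RunConfig, xyz_paths: Sequence, outdir,
                  axial_bump: Optional[tuple[float, float, float]] = None
                  ) -> list[Path]:
    """Generate synthetic ESP (+ density) cubes for XYZ inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in xyz_paths:
        mol = infer_roles(read_xyz(path), config.metals)
        spec = synthetic_spec_for(mol, axial_bump=axial_bump)
        req = grid_request_for_points(mol.coords, config.grid_spacing_bohr,
                                      config.grid_padding)
        spec = replace(spec, grid=req)
        esp = point_charge_field(spec)
        dens = gaussian_density(spec)
        stem = Path(path).stem
        esp_path = outdir / f"{stem}.esp.cube"
        dens_path = outdir / f"{stem}.dens.cube"
        write_cube(esp, mol, esp_path)
        write_cube(dens, mol, dens_path)
        written += [esp_path, dens_path]
    return written


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _result_record(name: str, mol: Molecule, res, meta: dict) -> dict:
    geo = geometry_descriptors(mol)
    return {
        "name": name,
        "metal": meta.get("metal", ""),
        "conformer": meta.get("conformer", ""),
        "pattern": meta.get("pattern", ""),
        "hemisphere": res.hemisphere,
        "status": res.status,
        "valid": res.valid,
        "z": res.candidate.z if res.candidate else np.nan,
        "V_candidate": res.candidate.V if res.candidate else np.nan,
        "Vs_max": np.nan if res.vs_max is None else res.vs_max,
        "V_hole_mean": res.v_hole_mean,
        "V_hole_max": res.v_hole_max,
        "V_hole_min": res.v_hole_min,
        "dV_hole": res.dv_hole,
        "dV_angle": res.dv_angle_deg,
        "tau4": geo.tau4,
        "mn_mean": geo.mn_mean,
        "alpha": geo.alpha,
        "beta": geo.beta,
    }


def analyze_pair(mol: Molecule, esp: ScalarGrid,
                 density: Optional[ScalarGrid], config: RunConfig,
                 name: str = "") -> list[dict]:
    """Analyze one complex/grid pair into descriptor records."""
    meta = dict(re.findall(r"(\w+)=(\S+)", mol.comment or ""))
    results = analyze_complex(mol, esp, density, config.detection_params())
    return [_result_record(name, mol, r, meta) for r in results]


def cmd_analyze(config: RunConfig,
                inputs: Sequence[tuple],
                out_csv) -> pd.DataFrame:
    """Run the π-hole analysis over (xyz, esp cube[, density cube]) tuples.

    Per-file failures are logged and skipped; an entirely failed run
    raises :class:`EmptyRunError`.
    """
    records: list[dict] = []
    n_ok = 0
    for item in inputs:
        xyz_path, esp_path = item[0], item[1]
        dens_path = item[2] if len(item) > 2 else None
        name = Path(xyz_path).stem
        try:
            mol = infer_roles(read_xyz(xyz_path), config.metals)
            esp, _ = read_cube(esp_path, kind="esp_kcalmol")
            density = None
            if dens_path is not None:
                density, _ = read_cube(dens_path, kind="density_au")
            records.extend(analyze_pair(mol, esp, density, config, name))
            n_ok += 1
        except Exception as exc:  # fault isolation: log and continue
            log.warning("analyze: %s failed: %s", name, exc)
    if n_ok == 0:
        raise EmptyRunError("no input pair could be analyzed")
    df = pd.DataFrame.from_records(records, columns=DESCRIPTOR_COLUMNS)
    if out_csv is not None:
        _write_csv(df, out_csv, DESCRIPTOR_SCHEMA)
    log.info("analyze: %d of %d inputs analyzed", n_ok, len(list(inputs)))
    return df


# ---------------------------------------------------------------------------
# grid sensitivity
# ---------------------------------------------------------------------------

_SENSITIVITY_DESCRIPTORS = ["Vs_max", "V_hole_mean", "V_hole_max",
                            "V_hole_min", "dV_hole"]


def cmd_grid_sensitivity(config: RunConfig,
                         spacings_bohr: Sequence[float] = (0.25, 0.20),
                         fixtures: Optional[Sequence[Fixture]] = None,
                         out_csv=None) -> pd.DataFrame:
    """Descriptor stability across grid spacings on the analytic suite.

    Re-generates every fixture's grids at each spacing, re-runs the full
    analysis, and reports the mean absolute percent deviation of each
    V-descriptor relative to the first spacing.
    """
    if len(spacings_bohr) < 2:
        raise ValueError("need at least two grid spacings to compare")
    if fixtures is None:
        fixtures = [f for f in fixture_suite() if f.name != "blocked_axis"]
    per_spacing: dict[float, pd.DataFrame] = {}
    for spacing in spacings_bohr:
        recs = []
        for fx in fixtures:
            esp, dens = make_grids(fx, spacing, config.grid_padding)
            recs.extend(analyze_pair(fx.molecule, esp, dens, config, fx.name))
        df = pd.DataFrame.from_records(recs, columns=DESCRIPTOR_COLUMNS)
        per_spacing[spacing] = df.set_index(["name", "hemisphere"])
    base = per_spacing[spacings_bohr[0]]
    rows = []
    for spacing in spacings_bohr[1:]:
        other = per_spacing[spacing]
        rec = {"spacing_bohr": spacing, "reference_bohr": spacings_bohr[0]}
        for col in _SENSITIVITY_DESCRIPTORS:
            a = base[col].astype(float)
            b = other[col].reindex(base.index).astype(float)
            mask = np.isfinite(a) & np.isfinite(b) & (np.abs(a) > 1e-9)
            dev = 100.0 * np.abs(b[mask] - a[mask]) / np.abs(a[mask])
            rec[f"mapd_{col}"] = float(dev.mean()) if mask.any() else np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out_csv is not None:
        _write_csv(out, out_csv, REPORT_SCHEMA)
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def cmd_report(descriptors: pd.DataFrame, out_csv=None) -> pd.DataFrame:
    """Aggregate descriptors per (metal, conformer) group.

    Occurrence % of validated π-holes, mean ± sd of |z| and V_hole,mean
    over validated rows, mean τ₄ and mean M–N distance over all rows.
    """
    required = {"metal", "conformer", "valid", "z", "V_hole_mean", "tau4",
                "mn_mean"}
    missing = required - set(descriptors.columns)
    if missing:
        raise KeyError(f"descriptor table missing columns: {sorted(missing)}")
    rows = []
    for (metal, conformer), grp in descriptors.groupby(["metal", "conformer"],
                                                       dropna=False):
        if len(grp) == 0:
            log.warning("report: empty group (%s, %s) omitted", metal, conformer)
            continue
        valid = grp[grp["valid"].astype(bool)]
        rows.append({
            "metal": metal,
            "conformer": conformer,
            "n_rows": len(grp),
            "occurrence_pct": 100.0 * len(valid) / len(grp),
            "z_mean": float(np.abs(valid["z"]).mean()) if len(valid) else np.nan,
            "z_sd": float(np.abs(valid["z"]).std(ddof=1)) if len(valid) > 1 else np.nan,
            "v_hole_mean_mean": float(valid["V_hole_mean"].mean()) if len(valid) else np.nan,
            "v_hole_mean_sd": float(valid["V_hole_mean"].std(ddof=1)) if len(valid) > 1 else np.nan,
            "tau4_mean": float(grp["tau4"].mean()),
            "mn_mean": float(grp["mn_mean"].mean()),
        })
    out = pd.DataFrame(rows)
    if out_csv is not None:
        _write_csv(out, out_csv, REPORT_SCHEMA)
    return out


def _write_csv(df: pd.DataFrame, path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(schema + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_schema_csv(path) -> pd.DataFrame:
    """Read a CSV written by this module (skips the schema comment)."""
    return pd.read_csv(path, comment="#")
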