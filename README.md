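# piholescan

Automated generation of {TM(cyclen)}²⁺ coordination-complex geometries
and detection of **metal-centered π-holes** on electrostatic-potential
(ESP) grids, using sector-based *relative* descriptors instead of the
absolute surface maximum V<sub>s,max</sub>.

## The problem

A π-hole is a region of locally enhanced (less negative / more
positive) electrostatic potential perpendicular to a molecular plane —
here, above a divalent first-row transition metal (Co, Ni, Cu, Zn)
bound in the pseudoplanar N₄ pocket of cyclen
(1,4,7,10-tetraazacyclododecane). Such axial electron depletion steers
directional binding of nucleophiles and anions. For charged complexes
the absolute surface maximum V<sub>s,max</sub> is a poor indicator: a
cation can be uniformly positive with no hole at all. What matters is
the potential of the axial maximum *relative to its own surroundings*.

`piholescan` implements the full workflow:

1. **Structure generation** — planar cyclen templates for the four
   unique N–H up/down (U/D) conformer classes (UUUU, DUUU, DDUU,
   DUDU), metalation at the N₄ centroid, combinatorial N-substitution
   with H/methyl/ethyl (root carbon at 1.47 Å along the former N–H
   vector, steric clashes < 0.8 Å resolved by 10° rigid rotations),
   and a 1.5 Å RMSD uniqueness filter. The default enumeration gives
   4 metals × 4 conformers × 3⁴ patterns = **1296 unique structures**.
2. **Frame alignment** — least-squares N₄-plane through the donor
   nitrogens; its normal n̂ is the molecular π-axis, and
   r<sub>aligned</sub> = (r − r<sub>centroid</sub>)·**Rot** maps every
   geometry and grid into a common frame.
3. **π-hole detection** — the ESP is interpolated every 0.05 Å along
   the π-axis up to 3 Å in both hemispheres inside a 1 Å cylinder;
   points with ∂V/∂r = 0 and ∂²V/∂r² < 0 are candidates. Each
   candidate is validated against eight 45° azimuthal background
   sectors (cylinder radius 2.5 Å, height ±0.25 Å, 1000 stratified
   samples per sector):

   V<sub>hole,mean</sub> = V − mean(V̄ᵢ) > Δ<sub>thr</sub> = 5 kcal mol⁻¹

   with V<sub>hole,max</sub> = V − min(V̄ᵢ), V<sub>hole,min</sub> =
   V − max(V̄ᵢ), anisotropy ΔV<sub>hole</sub> = max(V̄ᵢ) − min(V̄ᵢ)
   and its direction ΔV<sub>angle</sub>.
4. **Geometry descriptors** — the four-coordinate index
   τ₄ = [360° − (α + β)] / 141° (0 = square-planar, 1 = tetrahedral)
   and M–N distances.

ESP and electron-density grids come from Gaussian cube files written
by any QM stack, or from the built-in analytic generator (point-charge
Coulomb fields, Gaussian ESP features, model Gaussian densities) used
for testing and benchmarking. V<sub>s,max</sub> is evaluated on the
ρ = 0.001 e bohr⁻³ isodensity surface (marching cubes).

## Worked example

Generate the unsubstituted Zn/UUUU complex, attach a synthetic cation
ESP with a constructed axial feature, and analyze it:

```sh
piholescan generate demo --metals Zn --alphabet H
piholescan synth-esp demo/Zn_UUUU_H-H-H-H.xyz --outdir demo --bump 80 2.2 0.3
piholescan analyze demo/Zn_UUUU_H-H-H-H.xyz --out demo/descriptors.csv
piholescan report demo/descriptors.csv --out demo/report.csv
```

The descriptor CSV contains one row per hemisphere:

```
           name hemisphere       status    z  V_candidate  Vs_max  V_hole_mean  dV_hole  dV_angle  tau4
Zn_UUUU_H-H-H-H         +z    validated 1.95       244.29  230.65       134.03     2.65      45.0   0.0
Zn_UUUU_H-H-H-H         -z no_candidate  NaN          NaN  230.65          NaN      NaN       NaN   0.0
```

Reading: on the +z side the detector found an axial ESP maximum 1.95 Å
above the N₄-plane with a potential 134 kcal mol⁻¹ above its sector
background — a validated π-hole (the synthetic axial Gaussian placed
there). The near-zero anisotropy ΔV<sub>hole</sub> = 2.65 kcal mol⁻¹
reflects the axisymmetric field, and τ₄ = 0 the ideal planar template.
On the −z side the potential decays monotonically: no candidate.
V<sub>s,max</sub> (230.65) is the same for both rows — it is a global
surface property, which is exactly why it cannot diagnose the
hemisphere-specific hole.

Library use mirrors the CLI one-to-one:

```python
from piholescan import analyze_complex, read_cube, read_xyz
from piholescan.pipeline import infer_roles

mol = infer_roles(read_xyz("complex.xyz"))
esp, _ = read_cube("complex.esp.cube", kind="esp_kcalmol")
dens, _ = read_cube("complex.dens.cube", kind="density_au")
for result in analyze_complex(mol, esp, dens):
    print(result.hemisphere, result.status, result.v_hole_mean)
```

## Layout

```
src/piholescan/
  chemio.py     XYZ + Gaussian-cube I/O, Molecule/ScalarGrid, units
  structgen.py  conformers, templates, metalation, substitution, RMSD
  frame.py      N4-plane fitting, alignment, tau4, M-N descriptors
  espfield.py   synthetic fields, trilinear sampling, isosurfaces, Vs,max
  pihole.py     axial scan, sector validation, descriptor set
  fixtures.py   analytic benchmark fixtures with known ESP structure
  pipeline.py   batch commands, RunConfig, CSV schemas
  cli.py        click CLI: generate | synth-esp | analyze |
                grid-sensitivity | report
docs/methods.md the model, parameters, numerical choices, limitations
```
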