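# Methods

This note records the models, parameter choices and numerical details
behind `piholescan`, and what the synthetic benchmarks do and do not
demonstrate.

## Units

One internal unit system everywhere: lengths in Å, ESP in
kcal mol⁻¹ e⁻¹, electron density in e bohr⁻³. Cube files store bohr
and hartree; conversion happens only in `chemio` (0.52917721 Å/bohr,
627.5095 kcal mol⁻¹/hartree, Coulomb constant
332.0637 kcal Å mol⁻¹ e⁻²). Cubes already written in kcal/mol can be
read with `values_in_hartree=False`; hartree-in-cube is the default
convention.

## Structure generation

**Conformer classes.** N-substituent orientations are labelled by a
length-4 string over {U, D} in ring order. Two labels are equivalent
under ring rotation, ring reflection and a global U↔D flip (turning
the molecule over); the 16 strings collapse to four classes with
canonical representatives UUUU, DUUU, DDUU, DUDU (fewest D's, then
lexicographic). The test suite verifies this against an explicit
orbit-partition oracle.

**Templates.** The planar cyclen backbone places the 12 ring atoms on
a common circle with N–C 1.47 Å and C–C 1.54 Å (circumradius solved
numerically, ≈ 2.88 Å), CH₂ hydrogens by local tetrahedral
construction (C–H 1.09 Å), and N–H (1.02 Å) tilted 25° out of the
ring plane with the z-sign given by the U/D letter. Non-UUUU patterns
are equivalent to mirroring the corresponding hydrogen across the
ring plane. These internal values are free template parameters — the
structures are meant to be refined by external semiempirical/DFT
engines downstream — and were fixed once so that distinct substitution
patterns stay geometrically well separated (see *Uniqueness* below).

**Metalation** adds the metal at the arithmetic centroid of the four
donor nitrogens, sets the complex charge to +2 and the spin
multiplicity to the lowest value consistent with electron-count parity
(Co²⁺, Cu²⁺ → 2; Ni²⁺, Zn²⁺ → 1). Multiplicity is metadata for
engine-input stubs only; no electronic structure is computed here.

**Substitution.** The N–H hydrogen is removed and a rigid methyl or
ethyl template is attached with its root carbon 1.47 Å from N along
the former N–H unit vector. Methyl is tetrahedral C+3H; ethyl is a
staggered anti conformer (C–C 1.54 Å) whose arm is rotated 110° from
the azimuthal reference. The azimuthal reference frame is built from
the molecule itself (the nearest ring neighbour of the nitrogen,
projected perpendicular to the N→C axis), which makes substitution
equivariant under rigid motion of the input; an isolated N–H falls
back to a lab-frame basis. If any interatomic distance in the product
drops below 0.8 Å the substituent is rotated about the N→C axis in 10°
steps (0°, 10°, …, 350°, first passing angle wins); if no angle
passes, the structure is recorded as `rejected_overlap`. The overlap
test covers *all* atom pairs, not only pairs involving the new group.

**Uniqueness.** `rmsd` is the minimum per-atom RMSD after optimal
rigid superposition (Kabsch, via `scipy.spatial.transform.Rotation`)
with the canonical generated atom ordering — no graph-isomorphism
matching, since all structures come from one generator. `dedup` marks
the later row of any pair below 1.5 Å as `duplicate`. Comparisons are
restricted to rows of the same conformer class: conformer labels are
distinct stereochemical identities that share the planar template
backbone by construction (they differ only by mirrored substituent
vectors), so cross-conformer proximity of *unrefined templates* is a
property of the template, not an enumeration redundancy; a
`within_conformer=False` flag enables the wider comparison. With the
default template parameters the closest same-formula pair in the full
1296-structure set is 1.60 Å apart, so the enumeration is unique with
margin.

## Frame and geometry descriptors

The N₄-plane is the least-squares plane of the four donor nitrogens
(SVD of the centred positions; all four weighted equally). The
in-plane x-axis follows the shortest N–N difference vector projected
into the plane (lowest-index pair on ties); y completes a right-handed
triad with the normal n̂. The normal's sign is fixed deterministically
(dominant lab component positive); since `analyze_complex` scans both
hemispheres, the sign choice only labels results, never changes them.
Degenerate (collinear) nitrogen sets raise `FitError`.

τ₄ uses the standard normalisation [360° − (α + β)] / 141° with α ≥ β
the two largest donor–metal–donor angles, reaching 0 at square-planar
(α = β = 180°) and 1 at tetrahedral (α = β = 109.47°).

## Synthetic fields

`FieldSpec` describes analytic stand-ins for QM-derived volumetric
data: point charges (V = 332.0637·Σqᵢ/rᵢ), Gaussian ESP features
(amplitude kcal/mol, width Å) and Gaussian model densities (amplitude
e bohr⁻³, width bohr). Default grids are axis-aligned, 0.25 bohr
(0.13229 Å) spacing, padded 4 Å beyond the atoms, with the origin
anchored to the atom bounding box so that translating a system
translates its grid nodes identically. The Coulomb potential is
clamped inside 0.1 Å of a charge to avoid singular voxels; the clamp
only affects regions no detector samples (candidates live ≥ 0.5 Å
from nuclei in all fixtures).

These fields emulate the *shape* of a cationic complex's ESP — a
positive decaying envelope with or without a localized axial
enhancement — not any specific electronic structure. Benchmarks that
pass on them validate the detection geometry, the sampling estimators
and the descriptor algebra; they say nothing about DFT-level ESP
values of real complexes, which must be supplied as cube files.

The `axial_depletion` fixture places a narrow positive Gaussian
(amplitude 80 kcal/mol, width 0.25 Å) on the π-axis with its centre
solved (Brent root-finding on the analytic axial derivative) so the
composite profile's true maximum sits at exactly 2.100 Å — inside the
1.8–2.4 Å band where such axial features are physically relevant.

## Detection algorithm

**Axial scan.** 0.05 Å steps from the N₄ centroid to 3.0 Å per
hemisphere; V by trilinear interpolation. A point is flagged when the
discrete first derivative changes sign + → − and the central second
difference is negative; both derivative criteria use the same 0.05 Å
stencil (the source convention leaves the discretisation open).
Flagged points must also dominate eight lateral probes at 1.0 Å radius
and equal z (disable with `lateral_check=False`), which separates
axial maxima from off-axis ridges. On all analytic fixtures the
flagged z agrees with a dense 0.001 Å oracle on the closed-form
profile to within one scan step.

**Sector sampling.** Per sector, 1000 deterministic stratified points
uniform in the wedge volume (uniform in r², θ, z). The strata are
allocated radially-major — (n_r, n_θ, n_z) = (40, 5, 5) for n = 1000 —
because the background ESP varies far more strongly along the radius
(Coulombic decay plus feature tails) than azimuthally or vertically in
the thin wedge; a near-cubic 10×10×10 lattice biases sector means by
~1% when a sharp axial feature sits inside the innermost stratum,
while the radial-major lattice agrees with a 10⁶-sample Monte-Carlo
estimate to ≤ 0.5% on the fixture suite. The midpoint lattice is
mirror-symmetric between opposing sectors, so a linear field produces
exactly antisymmetric sector means. A seeded uniform-random sampler
(`sampler="random"`) exists for robustness testing; it carries ~2%
Monte-Carlo noise at 1000 samples. Out-of-grid samples are skipped,
with a hard error above 1% skipped per sector. The sector wedges span
the full radius 0→2.5 Å; an `inner_exclusion` radius (default 0) can
carve out the candidate cylinder if desired.

**Validation and descriptors.** The hole potential in every
V_hole formula is the *candidate's* local-maximum ESP value; the
global isosurface maximum V_s,max is computed separately (over the
marching-cubes vertex set of the ρ = 0.001 e bohr⁻³ surface, because
voxel-mask alternatives shift values by O(spacing)). A candidate is a
genuine π-hole iff V_hole,mean > 5 kcal mol⁻¹. ΔV_angle is the
minimal circular separation of the *centre* angles of the extreme
sectors, hence discrete in {0°, 45°, …, 180°}. `no_candidate` (no
axial maximum at all) and `failed_validation` (maximum present but
below threshold) are distinct statuses. When several maxima pass the
derivative criteria in one hemisphere, the highest-V one is validated
and the rest are kept unvalidated in `result.secondary`.

All relative descriptors are exactly invariant under adding a constant
to the ESP grid, while V_s,max shifts by exactly that constant — the
operational content of "an absolute surface maximum cannot diagnose a
π-hole on a charged system".

## Numerical accuracy and sensitivity

Trilinear interpolation is exact at voxel nodes and on linear fields
and second-order convergent otherwise (error ~ h²·V″/8). On the
default 0.13229 Å grid this is the dominant error source: for the
sharp synthetic axial feature it is a few kcal/mol at the candidate
point. Consequences, all measured in the test suite:

- Rigid motions that map the regenerated lab-aligned grid onto the
  moved original (right-angle rotations, arbitrary translations —
  origins follow the bounding box) reproduce descriptors to < 10⁻³
  kcal/mol. Generic-angle rotations reproduce them to interpolation
  accuracy (a few kcal/mol on the sharpest fixture).
- Refining the grid from 0.25 to 0.20 bohr changes V_s,max,
  V_hole,mean, V_hole,max and V_hole,min by well under 5% on the
  fixture suite. The spread ΔV_hole = max(V̄ᵢ) − min(V̄ᵢ) is
  intrinsically more grid-sensitive — on near-axisymmetric fields its
  magnitude is itself interpolation noise — so it is reported but not
  held to the 5% bound.

## Degenerate inputs and tie-breaks

- Rotation-scan ties: angles tried ascending from 0°, first pass wins.
- Shortest N–N vector ties in the frame: lowest donor-index pair.
- Sector extrema ties: `argmax`/`argmin` take the lowest sector index.
- Collinear donors, empty isosurfaces, non-orthogonal cube axes,
  MO-style negative-atom-count cubes and out-of-coverage scans all
  raise typed errors (`FitError`, `EmptySurfaceError`, `FormatError`,
  `CoverageError`) rather than returning silent values.

## Problem sizes used in the shipped benchmarks

The full default enumeration (1296 structures, ~3 s) is exercised
end-to-end, including the RMSD filter. Volumetric benchmarks use
single-complex grids of ~90³ voxels at 0.25 bohr (plus 0.20 bohr for
the sensitivity comparison) and 10⁶-sample Monte-Carlo sector oracles
on one fixture; these sizes were chosen as the smallest that expose
each estimator's error scaling cleanly.

## Known limitations

- No quantum chemistry: geometries are unrefined templates and
  synthetic fields are point charges + Gaussians. Real workflows must
  bring DFT-optimized geometries and Multiwfn/ORCA-style cubes.
- Only scalar-field cubes (one value per voxel); MO cubes are
  rejected.
- The RMSD filter assumes generator atom ordering; structures from
  other sources would need their own correspondence.
- The detector assumes a roughly planar four-donor pocket; it searches
  only the two π-axis hemispheres, not σ-hole directions along bonds.
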