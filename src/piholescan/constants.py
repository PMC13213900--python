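"""Physical constants and the internal unit system.

Everything inside the package uses a single unit system: lengths in
angstrom (Å), electrostatic potential in kcal mol⁻¹ e⁻¹, electron
density in e bohr⁻³.  Volumetric files on disk (Gaussian cube) use
atomic units; the I/O layer converts at the boundary.
"""

# Length conversion (CODATA, truncated to the precision used throughout).
BOHR_TO_ANGSTROM = 0.52917721
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# Energy-per-charge conversion for ESP values stored in cube files.
HARTREE_TO_KCALMOL = 627.5095

# Coulomb constant for point-charge potentials: V [kcal/mol/e] = K q / r[Å].
COULOMB_K = 332.0637

# Default grid conventions for synthetic volumetric fields.
DEFAULT_GRID_SPACING_BOHR = 0.25
DEFAULT_GRID_PADDING_ANGSTROM = 4.0

# Electron-density isosurface threshold conventionally used for
# molecular ESP surfaces.
DEFAULT_ISO_DENSITY = 0.001  # e bohr^-3
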