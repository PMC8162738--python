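# Methods

## Model

`excitube` treats a tubular dye aggregate as a set of N two-level
chromophores, each carrying a transition dipole of magnitude μ = q·l.
The collective excited states are eigenstates of the one-exciton
Frenkel Hamiltonian: site energies E₀ + Δε_n on the diagonal (E₀ the
gas-phase monomer excitation energy, Δε_n an environment-induced
shift), and resonance couplings J_nm off the diagonal.  Couplings are
evaluated in the extended dipole model — two transition charges ±q a
distance l apart along the molecular dipole axis — as the four-term
Coulomb sum over endpoint pairs.  In the far field this reduces to the
point-dipole kernel (verified to < 0.5 % of the kernel scale kμ²/r³
for r ≥ 20 l); at the sub-nm stacking distances of a dye aggregate the
two differ substantially, which is why the extended form is the
default.  Vibronic coupling is not included: the exciton bandwidth
(W ≈ 6–7·10³ cm⁻¹ for the reference structures) far exceeds the
vibronic energy scale, the regime in which vibronic side bands are
suppressed.

Working units: nm, elementary charges, cm⁻¹, e·nm for dipoles.  The
Coulomb prefactor k = e²/(4πε₀hc) = 1.16141·10⁴ cm⁻¹·nm·e⁻² is derived
from CODATA constants in `constants.py`.  An optional relative
screening constant divides all couplings (default 1, vacuum).

## Lattice construction and rolling

A 2D herringbone lattice (two molecules per cell, mirrored in-plane
orientations) is tiled and rolled onto a cylinder.  The rolling angle
θ is the angle between lattice vector a1 and the circumferential
direction.  Since 2πr is generally not a lattice translation, the
rolling vector is snapped to the nearest integer combination
m·a1 + n·a2; the circumference (hence radius) is rescaled accordingly.
The applied strain |R|/(2πr) − 1 is reported and limited to 1 %, and
the rolling direction may deviate up to 8° from the request (the
realized angle is reported in metadata and scan tables).  Exactly one
circumference is generated (half-open azimuthal interval, no seam
row).  Dipoles are rotated rigidly into the local tangent frame: a
planar dipole (d_u, d_v, d_n) becomes d_u·t̂(φ) + d_v·ẑ + d_n·n̂(φ)
with t̂ = (−sin φ, cos φ, 0) and n̂ = (cos φ, sin φ, 0).

**Axial boundaries.** Tubes are finite with open ends by default,
matching the finite (~100 nm) aggregates being modeled.  For *band
positions* of ideal tubes, open ends are a poor probe at accessible
sizes: the broken coupling chains at the ends shift the bright parallel
state by ~100 cm⁻¹ at N ≈ 1000 in a θ-dependent way, masking the bulk
property that the parallel band is insensitive to the rolling angle.
`build_tube(..., periodic_axial=True)` therefore snaps the tube length
to an axial lattice period and records the associated screw operation
(rotate by Δφ, translate by P); `build_hamiltonian(...,
axial_images=K)` adds couplings to K screw images on either side.
With K = 3 the parallel-band position of a 1000-site tube varies by
~4 cm⁻¹ over θ ∈ {20°, 30°, 40°, 55°} at r = 5.7 nm (a genuine
curvature effect of ~20 cm⁻¹ remains at the small 3.2 nm radius),
while the perpendicular band moves by hundreds of cm⁻¹ — the
structure-selection signal.  All ideal-band diagnostics
(`scan_rolling_angle`, `wall_peak_splitting`) use this screw-periodic
mode; disorder ensembles and structure files keep open ends unless
built otherwise.

A hard-core guard forbids transition-charge endpoints of different
molecules closer than 0.1 nm; violating geometries raise an error
(the guard constrains *inter-molecular* endpoint pairs, not the
intra-molecular charge separation l itself).

## Reference unit cell (documented placeholder) and extended dipole

The exact crystallographic cell of the C8S3 herringbone lattice is not
publicly tabulated, so the package ships a calibrated placeholder that
every user can override in the config:

    a1 = (1.70, 0) nm      slip direction of the long molecular axis
    a2 = (0, 0.92) nm      π-stacking rows
    basis at (0,0) and (½,½), in-plane orientations ±15° about a1,
    out-of-plane tilt 8°

The mirror symmetry of the basis about a1 makes the two sublattices
glide-equivalent; without it the ideal-structure coupling-sum
distribution is spuriously bimodal.  The cell area (1.56 nm², 0.78 nm²
per molecule) matches a ~7000-molecule double-walled tube at 100 nm
length.  The free parameters were calibrated once against the
aggregate-level observables of the C8S3 system: strongly negative
per-molecule coupling sums of order −3.5·10³ cm⁻¹ in the inner wall, a
total exciton bandwidth of order 6·10³ cm⁻¹, parallel-polarized
low-energy bands with the inner-wall band lowest, and the rolling-angle
phenomenology (parallel band θ-insensitive; parallel-to-perpendicular
oscillator-strength ratio increasing with θ, so small θ starves the
parallel bands and large θ starves the perpendicular band).  With the
default extended dipole q = 0.34 e, l = 0.70 nm (μ = 0.238 e·nm
≈ 11.4 D, mapped on the polymethine bridge), the bulk coupling-sum
means come out at −3510 (IW) and −3313 cm⁻¹ (OW at 2.4 % expansion).

Wall radii default to 3.2 nm (inner) and 5.7 nm (outer): the 2.5 nm
gap lies inside the 2.3–2.7 nm band that yields stable double-walled
structures, and assembly warns outside it.  Both walls use θ = 30°.
The outer-wall lattice is expanded in-plane by the config factor
1.024; with this cell that yields an inner–outer parallel-band
splitting of ~196 cm⁻¹, and the density scan's inverse lookup reports
the expansion that would match any target splitting (e.g. ~3.7 % for
300 cm⁻¹).

## Disorder models

**Diagonal (energetic) disorder.** Per-molecule Gaussian shifts with
per-wall mean and width; defaults mean 350 cm⁻¹ for both walls, widths
213 (IW) and 231 cm⁻¹ (OW) — the scale of microelectrostatic
solvent-shift distributions for this system.  Sampling is i.i.d. per
snapshot with seeds spawned deterministically from a master seed
(`numpy.random.SeedSequence`), so ensembles are bitwise reproducible.

**Structural disorder (MD surrogate).** Thermal packing disorder is
emulated by (i) a uniform packing relaxation — all coordinates scaled
about the centroid by `relaxation_scale`, default 1.02 in the config —
and (ii) i.i.d. Gaussian positional jitter (σ_pos = 0.05 nm per axis)
plus small-angle orientational jitter (angle ~ |N(0, σ)| about a
uniformly random axis, σ = 5°).  Coupling disorder is *emergent*: the
jittered geometries are re-translated into couplings, never prescribed
directly.  The relaxation component is essential to the phenomenology:
pure i.i.d. jitter systematically *deepens* the mean coupling sum
(convexity of r⁻³) and drags absorption weight into the low-energy
Lifshitz tail, i.e. it red-shifts the J-band, whereas equilibrated
structures have slightly looser packing than the idealized lattice,
weakening the mean coupling sum and blue-shifting the band.  With the
shipped defaults the surrogate reproduces the expected ensemble
behavior — broadened coupling-sum distributions with a less negative
mean, and a broadened, blue-shifted J-band (≈ +50 cm⁻¹ from structure
alone at σ_pos = 0.05 nm on a 500-site periodic tube).  Jitter is
uncorrelated between sites; correlated disorder is an extension hook.

What the surrogate does *not* emulate: anharmonic large-amplitude
motions, correlated acoustic-like fluctuations, wall-dependent stress
(real inner walls are more strained than outer ones), and any coupling
between structural and energetic disorder.  Tests passing under the
surrogate demonstrate correct machinery and qualitative response to
disorder, not quantitative agreement with molecular-dynamics
ensembles.

**Snapshot ingestion.** PDB/GRO/XYZ coordinates are read through
MDAnalysis; a mapping names two atoms (or weighted atom groups) per
residue as the polymethine-bridge endpoints; the site is their
midpoint, the dipole axis their normalized difference (coordinates
converted Å → nm).  XYZ files without residue records are chunked by a
fixed atom count per molecule.  Wall labels come from a radial
threshold (given, or the midpoint of the configured wall radii).

## Spectroscopy

Stick spectra resolve each eigenstate's collective dipole
μ_k = Σ_n c_kn μ_n into a parallel (z²) and perpendicular (x² + y²)
intensity, plus a diagnostic wall weight Σ_{n∈wall} c²_kn.  Broadening
is phenomenological: each stick is convolved with a unit-area
Lorentzian (default; Gaussian optional) of configurable FWHM (default
150 cm⁻¹), optionally different for the perpendicular channel.  The
auto grid spans the sticks ± 10 linewidths (2000 points); a supplied
grid that fails to cover the sticks ± 5 linewidths triggers a
truncation warning.  Integrated intensity equals the stick weight to
0.1 % on adequate grids.  Ensemble spectra are channel-wise means over
per-snapshot spectra on a common grid.  The wavelength view is a pure
reindexing λ = 10⁷/E with no Jacobian (spectra are reported per unit
energy); normalization default is max = 1, with an integrated-area
option.  Peaks are located by a prominence-filtered local-maximum
search (2 % of the channel maximum) with three-point parabolic
refinement; FWHMs by half-height crossings; the inner–outer splitting
is the distance of the two lowest-energy parallel peaks and the band
ratio integrates each over ±1.5 FWHM windows.

## Microelectrostatics

The solvent shift of a central dye is Δε = E_e − E_g: two evaluations
of the interaction energy between the central molecule (excited- or
ground-state atomic point charges) and the identical ground-state
environment within a 3.0 nm center-of-geometry carve-out.  Each
evaluation is electrostatic (pairwise Coulomb, cross terms only)
plus induction: environment atoms carry isotropic polarizabilities and
their induced dipoles p_i = α_i E_i are solved self-consistently for
*both* states (a stated assumption — the response is not treated
perturbatively).  The central molecule is described by charges only;
its own polarizabilities are not used.

The induction solver is a damped Jacobi iteration (damping 0.5,
tolerance 10⁻⁸ e·nm on the dipole update, 200 iterations max; a direct
linear solve serves as the oracle in tests; the one-site case is
solved in closed form).  Fields are measured in e/nm² so p = αE with α
in nm³; energies are converted by k.  A polarizable site is excluded
from the permanent field *and* the induced-dipole field of its own
molecule (atomic polarizabilities are parametrized for intermolecular
response; including intramolecular terms at bonded distances diverges).
Pairs of polarizable sites from different molecules closer than
(4α_iα_j)^(1/6) — where the undamped response has spectral radius ≥ 1
— trigger a polarization-catastrophe warning.  No periodic images;
finite clusters only.  Gaussian fits of per-wall shift distributions
(maximum likelihood, ≥ 10 samples, rms histogram residual reported)
parametrize the diagonal disorder model.

The packaged charge models are synthetic: a polymethine-like neutral
dumbbell whose excited state moves charge toward the bridge center,
three-point water with TIP3P-like charges, and Na⁺, all with
Thole-type atomic polarizabilities (C 1.334, O 0.837, H 0.496,
Na⁺ 0.157 ·10⁻³ nm³).  The solvated-cluster generator places randomly
oriented waters and ions in a shell around the dye with a 0.25 nm
clash rejection.  These exercise the full pipeline but do not
reproduce the shift statistics of the real chromophore.

## Delocalization

Per state, the delocalization size is the inverse participation ratio
N_k = 1/Σ_n c⁴_kn.  The scalar summary is the oscillator-strength-
weighted mean of N_k over a window centred on the brightest stick with
half-width half of the weighted FWHM (2.355 σ_w) of the stick
spectrum; the window is configurable.

## Numerical choices

Dense symmetric diagonalization (`numpy.linalg.eigh`) throughout — no
sparse path; N ≤ ~10⁴ fits comfortably in memory.  Hamiltonian
assembly is blocked (512 rows) over `scipy.spatial.cdist` distance
matrices and symmetrized exactly against rounding.  Coupling cutoff
default is none (all pairs); a radius cutoff is available for large
tubes.  Degenerate inputs fail loudly: parallel lattice vectors,
non-unit dipole axes, non-symmetric or non-finite Hamiltonians,
coincident mapped endpoints, sub-guard contacts.  Jitter draws
violating the endpoint guard are resampled up to 10 times, then raise.
Pair maps use the axis convention φ = arccos|d_i·d_j| ∈ [0°, 90°]
(orientation sign is a gauge), with default bins 0.05 nm × 2° up to
r_max = 3 nm.

Reported quantities use moderate problem sizes chosen for convenient
interactive use: ~400–1100-site single walls (screw-periodic for bulk
band positions), a ~1400-site double wall, 10–20-snapshot ensembles,
and 10⁴-sample disorder round trips; the acceptance script states the
size `n` next to every number it emits.

## Known limitations

* The reference unit cell is a calibrated placeholder, not the
  crystallographic cell; absolute band positions and splittings shift
  with the cell, which is why they are exposed as config values.
* Two-exciton states, annihilation, transport and lineshape theory
  from time-correlation functions are out of scope.
* The structural surrogate is i.i.d. plus a uniform relaxation; it has
  no correlation length and identical statistics for both walls.
* Screw-periodic image sums truncate at K images (default 3); the
  neglected tail shifts band positions by a few cm⁻¹.
* The DRF-style solver is isotropic and point-charge based; anisotropic
  polarizabilities and quantum/classical embedding are not modeled.
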