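# Methods

## The model

A molecule's van der Waals surface — taken as the 0.002 e bohr⁻³
electron-density isosurface — is divided into patches of equal area, and
each patch is replaced by one surface site interaction point (SSIP)
carrying a signed parameter ε derived from the molecular electrostatic
potential (MEPS) at the patch's most polar point. ε² is a molar energy, so
ε has units (kJ mol⁻¹)^½; positive values behave like hydrogen-bond donor
parameters (α), negative values like acceptor parameters (−β).

A liquid phase is the collection of all its components' SSIPs, each at a
normalised concentration θ = c/c_max, where c_max = 300 M is the maximum
theoretical SSIP density (from the 5 Å³ reference volume per site; a water
molecule encloses ~20 Å³ and carries four sites). All sites associate
pairwise 1:1:

    K_ij = exp(−(E_vdW + min(ε_i ε_j, 0)) / RT)

E_vdW = −5.6 kJ mol⁻¹ is the same for every pair because equal-area sites
make van der Waals energies approximately constant per contact. Like-sign
pairs are assumed to rotate their polar axes out of alignment, so only the
dispersive term survives — hence the `min(·, 0)`.

Speciation solves the coupled mass balances

    θ_i = f_i (1 + Σ_j K_ij f_j)

for the free-site populations f_i. Each i–j contact has population
K_ij f_i f_j (halved on the diagonal, since an i–i contact consumes two
copies of site i), which closes the balance exactly; the contact-matrix
conservation identity is asserted to 10⁻⁹ in the tests.

### Void handling

Unoccupied volume, θ_E = 1 − Σθ, is treated as an inert reference: it does
not participate in the speciation equilibria, and a probe site pairs with
it at K = 1 (ΔG = 0, no van der Waals term). The solvation free energy of
an idealised probe at infinite dilution is then

    ΔG_solv(ε) = −RT ln(θ_E + Σ_j K(ε, ε_j) f_j)

which is exactly zero in vacuum (θ_E = 1) for every probe — the gas phase
is the zero of the energy scale. The probe does not perturb the solvent
speciation (infinite-dilution contract). One consequence worth noting: in
a strongly hydrogen-bonded solvent the free-site populations are small, so
a nonpolar probe (ε = 0) can have ΔG_solv > 0 — the hydrophobic penalty of
carving a dispersive-only site out of a cohesive liquid — whereas in a
nonpolar liquid of the same density ΔG_solv(0) < 0. Both behaviours fall
out of the single formula above.

### FGIP bookkeeping

The functional group interaction profile reports the free-energy change of
bringing two dissolved probes into contact:

    ΔΔG_FGI(a, b) = ΔG_int(a, b) + ΔG_ss − ΔG_solv(a) − ΔG_solv(b)

with ΔG_int = E_vdW + min(ε_a ε_b, 0) the direct contact energy and ΔG_ss
the solvent-reorganisation credit, implemented as the population-weighted
mean solvation energy of the solvent's own sites (the solvent–solvent
contact recovered when two solvation shells merge). This is the minimal
bookkeeping with the right limits — in the gas phase ΔΔG reduces to
ΔG_int everywhere (so ΔΔG(0,0) = E_vdW), and the expression is symmetric
under probe exchange — and it is isolated in `applications.fgip_pair` so a
different convention can be substituted without touching the solver. Note
that the FGIP *matrix* is not symmetric: cell (i, j) is the probe pair
(+α_i, −β_j), so transposing the grid changes the pair; the symmetry law
ΔΔG(a, b) = ΔΔG(b, a) holds for the pair function.

### Solvent similarity index

Two phases are compared through their solvation profiles D_P(ε) =
ΔG_solv(ε | P) on a grid ε ∈ [−10, 5] in steps of 0.1. The default metric
is the uncentered cosine similarity of the two profile vectors: 1 for
identical solvation behaviour, decreasing as the profiles diverge. The
metric is pluggable. Degenerate cases: two empty (gas) phases compare as
1 (identical zero profiles); a gas phase against a dense phase is defined
as 0, since the cosine of a zero vector is undefined. For dense phases the
profiles are sign-coherent and the value falls in (0, 1].

## Footprinting choices

* **Per-SSIP area 9.35 Ų** (configurable). Chosen so a water-sized vdW
  surface (~37.4 Ų) yields exactly four sites, matching the four-site
  description of water that anchors c_max. The site count is
  max(1, round(area/9.35)) with banker's rounding.
* **Sign allocation.** The site count is split between the positive- and
  negative-MEPS point classes in proportion to their areas
  (largest-remainder rounding), so a strongly polar minority region cannot
  be swallowed by the majority class.
* **Greedy accretion.** Within a class, each patch seeds at the unclaimed
  point of largest |MEPS| (ties broken by coordinates for determinism) and
  accretes the nearest unclaimed in-class points until it reaches the
  class target area, class_area/quota; the last patch takes the class
  remainder. The target equals the nominal per-SSIP area up to point
  granularity, and by construction the patches tile the surface exactly,
  so patch areas balance and no leftover points need reassigning.
* **Site position = extremal point**, not patch centroid: the extremum is
  the interaction site; a centroid can fall off the surface.
* **Calibration curve.** The MEPS→ε map is a pluggable pair of polynomial
  branches constrained to map 0 → 0 and be monotone. The default is linear
  with slope 0.03 (kJ mol⁻¹)^(−½) on both branches, chosen so water-scale
  MEPS extrema (~±150 kJ mol⁻¹) give ε of hydrogen-bond-parameter
  magnitude (~±4.5). Quadratic coefficients from an external calibration
  can be supplied through `CalibrationCurve`.

## Surface extraction

Marching cubes (scikit-image) on the density grid, with vertices refined
to double precision by recomputing each lattice-edge crossing, so vertex
densities interpolate the iso-level to ~10⁻⁶ relative or better.
Per-vertex areas are one third of each incident triangle (conserves total
mesh area exactly; degenerate triangles contribute zero and are logged).
The MEPS is sampled at vertices by trilinear interpolation in fractional
grid coordinates, which also supports non-orthogonal voxel axes; cube
geometry (bohr, hartree) is converted to Å and kJ mol⁻¹ at this boundary
(1 bohr = 0.529177210903 Å, 1 hartree = 2625.4996 kJ mol⁻¹).

## Phase assembly

The tsv format carries only names and mole fractions, so molar volumes
live in the solvent library (components.tsv). Mixture molarity is the
ideal-mixing value c_mix = 1/Σ_k χ_k V_m,k; every site of component k
enters at θ = χ_k c_mix / c_max. Σθ > 1 is an over-packing error, and
mole fractions that do not sum to 1 (tolerance 10⁻⁶) are a hard parse
error rather than being renormalised.

## Numerics

* **Speciation solver:** damped fixed-point iteration
  f ← (1−d) f + d·θ/(1 + K f), d = 0.5, tolerance 10⁻¹² on the mass-balance
  residual, at most 10⁴ iterations. The iteration is a contraction for the
  K magnitudes these θ scales produce (up to ~10⁴); the solution is
  verified in tests against the single-species quadratic closed form and a
  dense two-species root-finder, and is independent of the damping factor
  to 10⁻⁸. Non-convergence raises with the residual history attached.
* **Tie-breaks** in patch seeding: (−|MEPS|, x, y, z) lexicographic.
* **Degenerate inputs:** empty phases are legal everywhere (they are the
  gas reference); zero-MEPS surfaces produce ε = 0 sites; zero-area
  vertices are dropped from surface samples.

## Synthetic fixtures and their limits

The generators produce analytic fields with closed-form oracles: Gaussian
densities (isosurface radius √ln(A/level)), softened point-charge
potentials (Coulomb values outside the 0.1 bohr softening radius), a
water-like spherical sample with two donor and two acceptor lobes at
tetrahedral directions, and a hand-written ethanol-like site set (labelled
synthetic). They exercise geometry, interpolation, coarse-graining and the
equilibrium engine, but they are not DFT electron densities: real MEPS
have anisotropic surfaces, and quantitative ε values for real molecules
additionally require the external quadratic calibration. Passing tests
therefore validate the machinery and the model's internal identities, not
agreement with experimental solvation data. Problem sizes were chosen as
the smallest that expose the relevant behaviour: 64³ grids for isosurface
accuracy (~2% area error), 2000-point surface samples for footprinting,
and 50-draw oracle sweeps for the solver.
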