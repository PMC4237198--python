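# Model and numerical methods

This document describes the physical model behind each correction term,
the parameters and their defaults, what the synthetic test systems
emulate, and the numerical choices made in the solvers.

Units: lengths in nm, charges in elementary charges e, energies in
kJ/mol.  The Coulomb prefactor is 1/(4πε₀) = 138.9354578 kJ mol⁻¹ nm e⁻².

## 1. Corrected charging free energy

The raw charging free energy `raw` of a guest (net charge `Q_G`) in an
environment (pure water `W`, or water plus a host cage) is obtained by
thermodynamic integration over a linear charge-scaling parameter λ.
Four corrections remove the dependence on the electrostatic scheme
(LS = lattice summation under periodic boundary conditions, BM =
Barker–Watts reaction field with molecule-based cutoff `R_C`) and on
the box size:

```
corrected = raw + dG_pol + dG_sum + dG_hs + dG_excl
```

The charging contribution to binding is `ΔΔG = corrected(host) −
corrected(water)`.  A successful correction makes `corrected`
independent of scheme and box, which is quantified by the
root-mean-square deviation over all scheme/box combinations.

## 2. dG_pol — continuum electrostatics (`chargecorr.poisson`)

`dG_pol` corrects for (i) the spurious solvent polarization induced by
artificial periodicity (LS) or cutoff truncation (BM) and (ii) the
difference between the water-model permittivity (66.6 for SPC) and the
experimental one (78.4).  It is the difference of two continuum
charging free energies of the same solute cavity:

* an ideal calculation: non-periodic, plain Coulomb, solvent
  permittivity 78.4;
* a scheme-mimicking calculation: periodic box of the simulated edge
  `L` with the LS or BM interaction kernel, solvent permittivity 66.6.

### Dielectric cavity

Solute atoms are spheres of radius `r_i` (permittivity 1) in a solvent
continuum.  Radii default to the atom/water-oxygen Lennard-Jones
minimum distance minus a 0.14 nm water probe radius; polar hydrogens
get 0.05 nm.  The bundled Lennard-Jones table contains generic
united-atom-scale values and is configurable per call.

### Finite-difference solver

∇·(ε∇φ) = −ρ/ε₀ is discretized with the standard 7-point stencil on a
regular grid (default spacing 0.05 nm).  Face permittivities are
sampled directly at face centers from the signed distance to the
nearest sphere surface (linear vacuum fraction across one cell,
harmonic mixing); sampling at faces rather than averaging cell values
roughly halves the first-order interface bias (Born-ion error 0.6% at
0.05 nm spacing).  Point charges are spread to the eight surrounding
nodes by trilinear (cloud-in-cell) weights, and potentials are gathered
at atom sites with the same weights, which cancels the grid
self-energy exactly when a vacuum-reference solve is subtracted (see
below).

The linear system is solved by Jacobi-preconditioned conjugate
gradients.  Iteration stops when the estimated charging energy changes
by less than 0.01 kJ/mol between checks (every 25 iterations) and the
relative residual is below 1e-8.  Periodic solves neutralize the
right-hand side (tinfoil background) and fix the zero-mean gauge;
non-periodic solves use Dirichlet ghost layers set to the analytic
Coulomb potential of the solute charges screened by the reference
permittivity.

### FFT solvers and the BM kernel

For periodic homogeneous problems the same discrete operator is
inverted spectrally; the LS kernel uses the exact finite-difference
stencil symbol (4/h²)Σᵢ sin²(kᵢh/2), so the FFT and FD solutions agree
to solver tolerance on the same grid.  The BM kernel adds the Fourier
transform of Δψ = (ψ_BM − 1/r) − (ψ_LS − 1/r), a smooth bounded
function (value −(1 + C_RF/2)/R_C − ξ_EW at r = 0), tabulated on the
grid with ψ_LS evaluated by Ewald summation.  Heterogeneous problems
under a non-Coulombic kernel are solved by a GMRES iteration on the
induced bound charge.

The BM charging free energy is assembled as
`ΔG_BM = ΔG_LS(FD) + ΔG_BM(FFT) − ΔG_LS(FFT)`, which cancels the
shared discretization error of the two spectral solves.

### Charging free energy

Every solve is paired with a vacuum solve (ε = 1 everywhere, same grid
and kernel); the environment potential is the difference, so grid
self-interactions cancel.  Charging is λ-linear in the continuum, so
the λ-integral reduces to a closed form: one half of the guest's
reaction potential acting on the guest plus the full host reaction
potential acting on the guest (host charges are present at full
strength throughout guest charging).

### Validation

The solver stack is validated in the test suite against the Born ion
(≤ 2% at 0.05 nm spacing), the cubic-lattice Wigner self-term
ξ = −2.837297/L (≤ 0.5%), an independent brute-force Ewald oracle
(≤ 1e−6), and the finite-size scaling law ξ·F/(2L)·(1 − 1/ε) (≤ 10%).

## 3. dG_sum — summation scheme (`chargecorr.summation`)

Simulation codes accumulate the solvent-generated potential at solute
sites atom-by-atom ("P-summation").  For neutral solvent molecules with
quadrupole-moment trace γ_s relative to their van der Waals site this
differs from molecule-based summation by a constant offset potential,
contributing linearly in `Q_G`:

* LS: `dG_sum = −Q_G γ_s N_w / (6 ε₀ L³)` — all `N_w` waters in the box
  contribute.  Nearly box-independent at constant water density.
* BM: only the ⟨N_v⟩ waters inside the cutoff sphere contribute,
  through the Laplacian of the reaction-field part of the kernel:
  `dG_sum = −Q_G γ_s C_RF ⟨N_v⟩ / (8π ε₀ R_C³)`, with
  `C_RF = 2(ε_RF − 1)/(2ε_RF + 1)`.  An optional box-population term of
  the LS form can be mixed in to emulate alternative conventions.

Defaults: γ_s = 0.0082 e nm² and ε_RF = 66.6 (SPC), stored in the
bundled `water_models.yaml`.  ⟨N_v⟩ can be estimated from water frames
with `estimate_n_in_cutoff`.  The remaining direct periodic guest–guest
term is neglected; `check_direct_term_negligible` warns when the
guest/box volume ratio makes that questionable.

## 4. dG_hs and dG_excl — pair potentials (`chargecorr.pairpot`)

The effective pair interaction kernels are:

* CB: ψ(r) = 1/r (plain Coulomb, non-periodic);
* LS: the periodic lattice-sum Green's function, evaluated by Ewald
  summation (real-space erfc images, reciprocal sum, neutralizing
  background; α = 3.5/L, reciprocal vectors with |n|² ≤ 64 by default,
  both configurable).  Its r → 0 residue is the Wigner self-potential
  ξ = −2.837297/L;
* BM: ψ(r) = 1/r + C_RF r²/(2R_C³) − (1 + C_RF/2)/R_C inside the
  cutoff (exactly zero at r = R_C), zero beyond.

`dG_hs` replaces the effective-scheme direct guest–host interaction by
the Coulombic one.  Because the guest–host energy is λ-linear, the TI
reduces to the per-λ ensemble average of the interaction-function
difference evaluated on sampled configurations; the result is exactly
zero for hosts without partial charges.  `dG_excl` removes the
non-Coulombic residue ψ(r) − 1/r acting between covalently excluded
guest atom pairs (first and second neighbours); it vanishes for
monoatomic guests and is small (≲ a few kJ/mol) for the compact guests
considered here.

## 5. Thermodynamic integration (`chargecorr.ti`)

`trapezoid_ti` integrates per-λ ⟨∂H/∂λ⟩ averages on the default
11-point uniform λ grid with the trapezoidal rule and propagates
per-point statistical errors in quadrature of the trapezoid weights.
`block_average_error` estimates the statistical error of a correlated
time series by block averaging, taking the plateau (maximum) of the
block-error curve over block sizes; it reduces to the standard error
for uncorrelated data and inflates appropriately for autocorrelated
series.

## 6. Reporting (`chargecorr.report`, `chargecorr.io`)

`CorrectionLedger` enforces the additive identity on construction and
revalidates it on file read (tolerance 0.15 kJ/mol for tables printed
at 0.1 kJ/mol precision; exact for freshly assembled ledgers).
Consistency statistics use the population convention (rmsd about the
mean with divisor N).  Printed tables round half away from zero to
0.1 kJ/mol.  Combination statistics pair every water-leg box with
every host-leg box *within* a scheme (schemes never mix), and the
union set is the concatenation of the per-scheme pairings, so the union
mean is the count-weighted mean of the per-scheme means.

The solvent/host decomposition splits `raw` into a host part — the TI
integral of the λ-derivative of the guest–host cross energy, obtained
from energies evaluated with (total, guest-only, host-only) charge
toggles — and a solvent remainder.  The cross energy is λ-linear, so
its derivative is `(total − guest − host)/λ`, linearly extrapolated to
λ = 0 from the first two charged states.  `dG_hs` attaches to the host
part; `dG_pol`, `dG_sum`, `dG_excl` to the solvent part.

## 7. Solvent structure (`chargecorr.profiles`)

g(r) of water oxygens and the radial polarization P(r) (per-shell sum
of dipole-moment projections on the outward radial direction, divided
by shell volume) are accumulated around either the cage center of mass
or the guest's charge-bearing center.  Counting includes all periodic
images within √3·L/2 so profiles stay normalized out to the box corner.
The continuum reference is the Born polarization
P(r) = Q(1 − 1/ε)/(4πr²).  Default bin width 0.01 nm; the convention is
outward-positive, so cations give positive P near contact.

## 8. Synthetic test systems (`chargecorr.fixtures`)

Real host–guest trajectories are outside the scope of this package, so
the fixtures provide deterministic stand-ins with the same structural
logic:

* a truncated-icosahedron cage of 60 carbon vertices (90 bonds of
  0.2 nm), bare (CAPO) or functionalized with a neutral polar group
  (CHB), a +1 methylammonium-like group (CPOS), or a −1 formate-like
  group (CNEG);
* a +1 methylammonium-like guest (MAM) and a −1 acetate-like guest
  (ACE), placed with the charge-bearing center at the cage center;
* SPC-geometry water frames with uniform oxygen placement, optional
  solute clearance, and random or radially aligned dipole
  orientations;
* synthetic λ-series with prescribed integral, curvature, and seeded
  Gaussian noise for round-trip tests.

Partial charge sets reproduce the intended net charges with sensible
polarities but are package defaults, not values of any specific force
field.  All generators are deterministic given a seed.

## 9. Limitations

* The continuum model uses sharp spherical cavities and a local
  dielectric; it cannot capture molecular-scale solvent structure, so
  computed `dG_pol` values depend on the chosen radii.
* The van der Waals and standard-state contributions to binding, and
  the raw charging simulations themselves, are out of scope; raw values
  enter as inputs.
* The summation correction neglects the direct periodic guest–guest
  term (volume-ratio warning provided) and treats γ_s as
  configuration-independent.
* The BM continuum solve assumes `R_C ≤ L/2`; larger cutoffs are
  rejected.
* Finite-difference accuracy is first order at dielectric interfaces;
  the defaults (0.05 nm spacing) balance accuracy against runtime, and
  convergence should be checked when radii or geometries differ
  substantially from the bundled systems.
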