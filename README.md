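# chargecorr

Methodology corrections for the charging free energy of a charged guest
molecule bound inside a host cavity, computed from explicit-solvent
molecular simulations.

## The problem

The reversible work of switching on a solute's partial charges — the
*charging free energy* — is a central ingredient of host–guest binding
free energies.  When the guest carries a net charge, the raw value
obtained from a simulation depends strongly on how the simulation
handles electrostatics:

* **LS (lattice summation)** — Ewald-type summation over an infinite
  periodic lattice of box images.  The guest interacts spuriously with
  its own periodic copies and with a neutralizing background, and the
  solvent is over- or under-polarized depending on the box size.
* **BM (Barker–Watts reaction field)** — pair interactions truncated at
  a molecule-based cutoff `R_C` and augmented by the field of a
  dielectric continuum outside the cutoff sphere.  The truncation
  distorts the solvent polarization around the charged guest.

On top of the scheme-specific artifacts, both approaches use a water
model whose dielectric permittivity (≈ 66.6 for SPC) differs from that
of real water (≈ 78.4), and both accumulate the solvent potential
atom-by-atom rather than molecule-by-molecule, which introduces an
offset proportional to the water model's quadrupole-moment trace.

The result: raw charging free energies for the same guest in the same
environment can differ by tens of kJ/mol between schemes and box sizes.
This package computes the four corrections that remove these artifacts,

```
corrected = raw + dG_pol + dG_sum + dG_hs + dG_excl
```

* `dG_pol` — spurious solvent polarization and wrong model
  permittivity, from the difference of two continuum-electrostatics
  charging calculations: an ideal macroscopic Coulombic one and one
  mimicking the simulated (periodic or truncated) conditions.
* `dG_sum` — the atom-based vs molecule-based summation offset, in
  closed form.
* `dG_hs` — replaces the effective-scheme guest–host direct interaction
  by the true nonperiodic Coulombic one, averaged over sampled
  configurations.
* `dG_excl` — removes residual effective-scheme (non-Coulombic)
  interactions between covalently excluded guest atom pairs.

After correction, values obtained with different schemes and box sizes
collapse onto a common, methodology-independent estimate, and the
charging contribution to binding is the difference between the
host-environment and pure-water legs of the thermodynamic cycle.

## What the package provides

* A finite-difference Poisson solver on a regular grid with a
  heterogeneous dielectric (vacuum solute cavity in a dielectric
  continuum), under periodic or non-periodic boundary conditions, plus
  FFT-based solvers with exact lattice-summation and reaction-field
  kernels (`chargecorr.poisson`).
* Closed-form summation corrections for both schemes
  (`chargecorr.summation`).
* Effective pair potentials (Ewald, Barker–Watts, plain Coulomb) and
  the configuration-averaged `dG_hs` / `dG_excl` corrections
  (`chargecorr.pairpot`).
* Trapezoidal thermodynamic integration with error propagation and
  block-average statistical errors (`chargecorr.ti`).
* Thermodynamic-cycle bookkeeping: correction ledgers, binding
  contributions, consistency statistics over scheme/box combinations,
  and solvent/host decompositions (`chargecorr.report`).
* Solvent-structure diagnostics g(r) and radial polarization P(r) with
  the Born continuum analog (`chargecorr.profiles`).
* Synthetic but fully deterministic test systems: a 60-vertex
  fullerene-like cage (bare, or functionalized with neutral-polar, +1,
  or −1 groups), methylammonium-like (+1) and acetate-like (−1) guests,
  and SPC-geometry water configurations (`chargecorr.fixtures`).
* File I/O for PDB/GRO coordinates, a plain-text charge/topology
  sidecar, ledger CSV tables, and bundled benchmark tables
  (`chargecorr.io`), plus a `chargecorr` command-line interface.

Units throughout: nm, elementary charges, kJ/mol.

## Worked example

The closed-form summation correction for a +1 guest in 800 SPC waters
(cubic box, edge 2.90 nm) under lattice summation, and the cutoff-based
variant with 380 waters inside a 1.4 nm cutoff:

```
$ chargecorr correct sum --scheme LS --Q 1.0 --Nw 800 --L 2.9
dG_sum(LS) = -78.27 kJ/mol
$ chargecorr correct sum --scheme BM --Q 1.0 --Nv 380 --RC 1.4
dG_sum(BM) = -77.12 kJ/mol
```

The polarization/permittivity correction for a +1 ion of cavity radius
0.2 nm simulated with lattice summation in a 2.4 nm box, from two
continuum solves (non-periodic at permittivity 78.4 minus periodic at
the model permittivity 66.6):

```python
import numpy as np
from chargecorr import SchemeSpec, SoluteAtom, SoluteStructure, dG_pol

ion = SoluteStructure([SoluteAtom(name="NA", element="Na", position=np.zeros(3),
                                  charge=1.0, radius=0.2)], label="ion")
spec = SchemeSpec("LS", box_edge_L=2.4)
print(f"dG_pol(LS, L=2.4 nm) = {dG_pol(ion, spec, 'LS', spacing=0.08):.1f} kJ/mol")
```

prints

```
dG_pol(LS, L=2.4 nm) = -80.9 kJ/mol
```

Consistency statistics of the corrected binding contribution over all
in-scheme (water-box, host-box) pairings, from the bundled benchmark
ledgers for the +1 guest bound in the −1 cage:

```python
from chargecorr.io import load_benchmark_ledgers
from chargecorr import combination_stats, round_report

ledgers, flags = load_benchmark_ledgers()
water = {l.scheme_tag: l for l in ledgers if l.guest == "MAM" and l.environment == "W"}
host = {l.scheme_tag: l for l in ledgers if l.guest == "MAM" and l.environment == "CNEG"}
for ss in ("LS", "BM", "LS+BM"):
    m, r, n = combination_stats(water, host, ss)
    print(f"{ss:6s} mean = {round_report(m):7.1f}  rmsd = {round_report(r):4.1f}  n = {n}")
```

prints

```
LS     mean =   -67.6  rmsd =  2.0  n = 16
BM     mean =   -62.6  rmsd =  1.4  n = 4
LS+BM  mean =   -66.6  rmsd =  2.8  n = 20
```

The raw (uncorrected) binding contributions for the same system spread
over tens of kJ/mol between the 20 combinations; after correction the
spread collapses to 2.8 kJ/mol.

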