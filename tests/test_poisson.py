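import numpy as np
import pytest

from chargecorr.constants import COULOMB_FACTOR
from chargecorr.core import SchemeSpec, SoluteAtom, SoluteStructure
from chargecorr.fixtures import FixtureRecipe, build_complex, build_guest
from chargecorr.poisson import (
    _cic_gather,
    assign_radii,
    build_grid,
    charging_free_energy_continuum,
    dG_pol,
    kernel_hat_bm,
    kernel_hat_ls,
    solve_kernel_fft,
    solve_poisson_fd,
)

from conftest import make_ion

F = COULOMB_FACTOR


def test_assign_radii_from_lj_minima():
    mam = assign_radii(build_guest("MAM"))
    by_name = {a.name: a for a in mam.atoms}
    assert by_name["N"].radius == pytest.approx(0.345 - 0.14)
    assert by_name["CH3"].radius == pytest.approx(0.408 - 0.14)
    for name in ("H1", "H2", "H3"):
        assert by_name[name].radius == pytest.approx(0.05)


def test_assign_radii_rejects_unknown_or_too_small():
    s = SoluteStructure([SoluteAtom(name="X", element="Xx", position=np.zeros(3),
                                    charge=0.0)])
    with pytest.raises(KeyError):
        assign_radii(s)
    with pytest.raises(ValueError):
        assign_radii(s, lj_table={"Xx": 0.10})  # below the water probe radius


def test_build_grid_shapes_and_charge_conservation(ion):
    g = build_grid(ion, 2.4, 78.4, 0.1, "PBC")
    assert g.eps.shape == (24, 24, 24)
    assert g.charge.sum() == pytest.approx(1.0)  # CIC conserves total charge
    assert g.eps.min() >= 1.0 and g.eps.max() <= 78.4
    vac = build_grid(ion, 2.4, 78.4, 0.1, "PBC", vacuum=True)
    assert np.all(vac.eps == 1.0)


def test_npbc_vacuum_solve_matches_coulomb_at_distance(ion):
    L = 2.4
    g = build_grid(ion, L, 1.0, 0.05, "NPBC", vacuum=True)
    phi = solve_poisson_fd(g, boundary_eps=1.0)
    probe = g.positions[0] + np.array([0.8, 0.0, 0.0])
    val = _cic_gather(phi, probe[None, :], g.n, g.spacing, False)[0]
    assert val == pytest.approx(F / 0.8, rel=0.01)


def test_fd_and_fft_solvers_agree_on_heterogeneous_system(ion):
    L = 2.4
    g = build_grid(ion, L, 66.6, L / 32, "PBC")
    phi_fd = solve_poisson_fd(g)
    phi_fft = solve_kernel_fft(g, kernel_hat_ls(g.n, g.spacing))
    diff = phi_fd - phi_fft
    diff -= diff.mean()
    assert np.abs(diff).max() < 1e-3


def test_ls_charging_approaches_macroscopic_limit_with_box_size():
    ion = make_ion(radius=0.2, charge=1.0)
    cb = charging_free_energy_continuum(
        ion, SchemeSpec("CB", box_edge_L=3.2, eps_experimental=66.6), "CB",
        spacing=0.08)
    diffs = []
    for L in (2.4, 3.2, 4.8):
        ls = charging_free_energy_continuum(
            ion, SchemeSpec("LS", box_edge_L=L), "LS", spacing=0.08)
        diffs.append(abs(ls - cb))
    assert diffs[0] > diffs[1] > diffs[2]
    # the finite-size defect follows the Wigner law xi*F/(2L)*(1-1/eps)
    wigner = [2.837297 * F / (2 * L) * (1 - 1 / 66.6) for L in (2.4, 3.2, 4.8)]
    for d, w in zip(diffs, wigner):
        assert d == pytest.approx(w, rel=0.1)


def test_bm_charging_is_less_negative_than_ls_for_small_cutoff():
    # truncating solvent response at R_C loses solvation relative to LS
    ion = make_ion(radius=0.2, charge=1.0)
    spec = SchemeSpec("BM", box_edge_L=3.0, cutoff_RC=1.4)
    bm = charging_free_energy_continuum(ion, spec, "BM", spacing=3.0 / 40)
    ls = charging_free_energy_continuum(
        ion, SchemeSpec("LS", box_edge_L=3.0), "LS", spacing=3.0 / 40)
    assert bm > ls
    assert bm < 0.0


def test_bm_kernel_requires_cutoff_within_half_box():
    spec = SchemeSpec("BM", box_edge_L=2.4, cutoff_RC=1.4)
    with pytest.raises(ValueError):
        kernel_hat_bm(24, 0.1, 2.4, spec)


def test_dg_pol_sign_and_charge_symmetry_for_born_ion():
    # periodicity plus the lower model permittivity underestimate the
    # magnitude of solvation, so CB - LS is negative for a bare ion ...
    ion = make_ion(radius=0.2, charge=1.0)
    spec = SchemeSpec("LS", box_edge_L=2.4)
    val = dG_pol(ion, spec, "LS", spacing=0.08)
    assert val < 0.0
    # ... and, being quadratic in the charge, is invariant under inversion
    anion = make_ion(radius=0.2, charge=-1.0)
    assert dG_pol(anion, spec, "LS", spacing=0.08) == pytest.approx(val, rel=1e-9)
    with pytest.raises(ValueError):
        dG_pol(ion, spec, "CB")


def test_dg_pol_complex_runs_and_corrections_have_reported_sign(mam_capo):
    # uncharged host: correction dominated by the guest ion, negative for MAM
    spec = SchemeSpec("LS", box_edge_L=2.8)
    val = dG_pol(mam_capo, spec, "LS", spacing=0.1)
    assert val < 0.0


def test_uncharged_guest_costs_nothing():
    cage = assign_radii(build_complex(FixtureRecipe(host="CAPO", guest="MAM", seed=2)))
    neutral = cage.with_scaled_guest_charges(0.0)
    spec = SchemeSpec("LS", box_edge_L=2.8)
    assert charging_free_energy_continuum(neutral, spec, "LS", spacing=0.1) == 0.0


def test_radii_required_before_continuum_solves(ion):
    bare = make_ion(radius=0.0)
    with pytest.raises(ValueError):
        charging_free_energy_continuum(bare, SchemeSpec("LS", box_edge_L=2.4), "LS")
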