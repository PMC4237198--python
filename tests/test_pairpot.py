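import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chargecorr.core import DEFAULT_LAMBDAS, LambdaSeries, SchemeSpec
from chargecorr.fixtures import FixtureRecipe, build_complex
from chargecorr.pairpot import (
    dG_excl,
    dG_hs,
    guest_env_energy,
    psi,
    psi_minus_coulomb,
    reaction_field_constant,
    wigner_self_potential,
)


def test_coulomb_kernel_is_inverse_distance():
    spec = SchemeSpec("CB", box_edge_L=3.0)
    assert psi("CB", np.array([1.0, 0.0, 0.0]), spec) == pytest.approx(1.0)
    assert psi("CB", np.array([0.0, 0.5, 0.0]), spec) == pytest.approx(2.0)


def test_reaction_field_constant_limits():
    assert reaction_field_constant(1.0) == pytest.approx(0.0)
    assert reaction_field_constant(66.6) == pytest.approx(2 * 65.6 / (2 * 66.6 + 1))
    # conducting-boundary limit -> 1
    assert reaction_field_constant(1e9) == pytest.approx(1.0, abs=1e-6)


def test_bm_kernel_closed_form_inside_cutoff():
    spec = SchemeSpec("BM", box_edge_L=3.8, cutoff_RC=1.4)
    crf = reaction_field_constant(66.6)
    r = 0.9
    expected = 1 / r + crf * r**2 / (2 * 1.4**3) - (1 + crf / 2) / 1.4
    assert psi("BM", np.array([r, 0, 0]), spec) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(eps=st.floats(1.0, 200.0), rc=st.floats(0.8, 1.8))
def test_bm_kernel_continuous_at_any_cutoff(eps, rc):
    spec = SchemeSpec("BM", box_edge_L=4.0, cutoff_RC=rc, eps_reaction_field=eps)
    at_cut = psi("BM", np.array([rc, 0.0, 0.0]), spec)
    assert abs(at_cut) < 1e-12


def test_zero_separation_is_singular():
    spec = SchemeSpec("BM", box_edge_L=3.0)
    with pytest.raises(ValueError):
        psi("BM", np.zeros(3), spec)
    with pytest.raises(ValueError):
        psi("CB", np.zeros(3), spec)


def test_ls_kernel_periodicity_and_symmetry():
    L = 2.9
    spec = SchemeSpec("LS", box_edge_L=L)
    r = np.array([0.4, -0.7, 0.2])
    base = psi("LS", r, spec)
    for shift in (np.array([L, 0, 0]), np.array([0, -L, L])):
        assert psi("LS", r + shift, spec) == pytest.approx(base, abs=1e-8)
    assert psi("LS", -r, spec) == pytest.approx(base, abs=1e-10)


def test_ls_residue_limit_is_wigner_self_potential():
    L = 2.9
    spec = SchemeSpec("LS", box_edge_L=L)
    xi = wigner_self_potential(L)
    assert xi == pytest.approx(-2.837297 / L, rel=1e-4)
    tiny = psi_minus_coulomb("LS", np.array([1e-6, 0, 0]), spec)
    assert tiny == pytest.approx(xi, abs=1e-6)


def test_bm_residue_forms():
    spec = SchemeSpec("BM", box_edge_L=3.8, cutoff_RC=1.4)
    crf = reaction_field_constant(66.6)
    at_zero = psi_minus_coulomb("BM", np.zeros(3), spec)
    assert at_zero == pytest.approx(-(1 + crf / 2) / 1.4, abs=1e-12)
    beyond = psi_minus_coulomb("BM", np.array([1.6, 0, 0]), spec)
    assert beyond == pytest.approx(-1 / 1.6, abs=1e-12)


def test_guest_env_energy_linear_in_lambda(mam_cneg):
    spec = SchemeSpec("LS", box_edge_L=3.0)
    full = guest_env_energy(mam_cneg, 1.0, "LS", spec)
    half = guest_env_energy(mam_cneg, 0.5, "LS", spec)
    assert half == pytest.approx(0.5 * full, rel=1e-12)
    assert guest_env_energy(mam_cneg, 0.0, "LS", spec) == 0.0


def _rigid_series(s, n_frames=1):
    configs = [[s] * n_frames for _ in DEFAULT_LAMBDAS]
    return LambdaSeries(DEFAULT_LAMBDAS, np.zeros_like(DEFAULT_LAMBDAS),
                        configs=configs)


def test_dg_hs_zero_for_uncharged_host(mam_capo):
    spec = SchemeSpec("LS", box_edge_L=3.0)
    assert dG_hs(_rigid_series(mam_capo), "LS", spec) == pytest.approx(0.0, abs=1e-12)


def test_dg_hs_sign_for_oppositely_charged_complex(mam_cneg):
    # LS reduces the (attractive, negative) guest-host interaction relative
    # to plain Coulomb, so the correction CB - LS must be negative here.
    spec = SchemeSpec("LS", box_edge_L=3.0)
    value = dG_hs(_rigid_series(mam_cneg), "LS", spec)
    assert value < 0.0
    with pytest.raises(ValueError):
        dG_hs(_rigid_series(mam_cneg), "CB", spec)


def test_dg_hs_requires_configs(mam_cneg):
    series = LambdaSeries(DEFAULT_LAMBDAS, np.zeros_like(DEFAULT_LAMBDAS))
    with pytest.raises(ValueError):
        dG_hs(series, "LS", SchemeSpec("LS", box_edge_L=3.0))


def test_dg_excl_uses_only_guest_pairs(mam_cneg):
    spec_bm = SchemeSpec("BM", box_edge_L=3.8, cutoff_RC=1.4)
    value = dG_excl(mam_cneg, "BM", spec_bm)
    # manual oracle over the guest exclusion list
    crf = reaction_field_constant(66.6)
    pos, q = mam_cneg.positions, mam_cneg.charges
    expected = 0.0
    for i, j in mam_cneg.guest_exclusion_pairs():
        r = float(np.linalg.norm(pos[i] - pos[j]))
        resid = crf * r**2 / (2 * 1.4**3) - (1 + crf / 2) / 1.4
        expected -= 138.9354578 * q[i] * q[j] * resid
    assert value == pytest.approx(expected, rel=1e-12)
    assert value != 0.0


def test_dg_excl_magnitude_is_small_for_guests(mam_cneg):
    for scheme, L in (("LS", 3.0), ("BM", 3.8)):
        spec = SchemeSpec(scheme, box_edge_L=L, cutoff_RC=1.4)
        assert abs(dG_excl(mam_cneg, scheme, spec)) < 5.0
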