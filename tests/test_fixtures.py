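import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chargecorr.fixtures import (
    FixtureRecipe,
    build_buckyball,
    build_complex,
    build_guest,
    build_water_frame,
    complete_exclusions,
    synth_lambda_series,
)
from chargecorr.ti import trapezoid_ti


def test_bare_cage_topology_and_geometry():
    s = build_buckyball(FixtureRecipe(host="CAPO"))
    assert s.n_atoms == 60
    assert len(s.bonds) == 90
    assert s.net_charge() == pytest.approx(0.0)
    pos = s.positions
    for i, j in s.bonds:
        assert np.linalg.norm(pos[i] - pos[j]) == pytest.approx(0.2, abs=1e-9)
    center = pos.mean(axis=0)
    radii = np.linalg.norm(pos - center, axis=1)
    assert np.ptp(radii) < 1e-9  # icosahedral symmetry: all vertices equidistant


def test_functionalized_cage_net_charges():
    assert build_buckyball(FixtureRecipe(host="CHB")).net_charge() == pytest.approx(0.0)
    assert build_buckyball(FixtureRecipe(host="CPOS")).net_charge() == pytest.approx(1.0)
    assert build_buckyball(FixtureRecipe(host="CNEG")).net_charge() == pytest.approx(-1.0)


def test_unknown_host_rejected():
    with pytest.raises((ValueError, KeyError)):
        build_buckyball(FixtureRecipe(host="XXXX"))


def test_guest_charges_and_exclusions():
    mam = build_guest("MAM")
    assert mam.net_charge() == pytest.approx(1.0)
    ace = build_guest("ACE")
    assert ace.net_charge() == pytest.approx(-1.0)
    # every bonded pair and every 1-3 pair is excluded
    excl = complete_exclusions(mam)
    for i, j in mam.bonds:
        assert frozenset((i, j)) in excl


def test_complex_placement_and_net_charge():
    cplx = build_complex(FixtureRecipe(host="CNEG", guest="MAM", seed=1))
    assert cplx.net_charge() == pytest.approx(0.0)
    assert build_complex(FixtureRecipe(host="CNEG", guest="ACE", seed=1)
                         ).net_charge() == pytest.approx(-2.0)
    # guest charge-bearing centre at the cage centre of mass
    host_com = cplx.positions[cplx.host_indices][:60].mean(axis=0)
    first_guest = cplx.positions[cplx.guest_indices[0]]
    assert np.linalg.norm(first_guest - host_com) < 1e-9
    # no steric clash
    gpos = cplx.positions[cplx.guest_indices]
    hpos = cplx.positions[cplx.host_indices]
    d = np.linalg.norm(gpos[:, None, :] - hpos[None, :, :], axis=-1)
    assert d.min() >= 0.12


def test_complex_determinism_and_jitter():
    a = build_complex(FixtureRecipe(host="CAPO", guest="MAM", seed=5))
    b = build_complex(FixtureRecipe(host="CAPO", guest="MAM", seed=5))
    assert np.array_equal(a.positions, b.positions)
    j = build_complex(FixtureRecipe(host="CAPO", guest="MAM", seed=5,
                                    jitter_sigma=0.005))
    assert not np.array_equal(a.positions, j.positions)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(target=st.floats(-500, 500), curvature=st.floats(-50, 50))
def test_synth_series_integrates_to_target(target, curvature):
    series = synth_lambda_series(target, curvature=curvature, noise_sigma=0.0)
    assert trapezoid_ti(series).value == pytest.approx(target, abs=1e-9)


def test_synth_series_noise_determinism():
    a = synth_lambda_series(-100.0, noise_sigma=2.0, seed=42)
    b = synth_lambda_series(-100.0, noise_sigma=2.0, seed=42)
    c = synth_lambda_series(-100.0, noise_sigma=2.0, seed=43)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)
    with pytest.raises(ValueError):
        synth_lambda_series(-100.0, noise_sigma=-1.0)


def test_water_frame_geometry_and_solute_clearance():
    frame = build_water_frame(50, 2.5, seed=3)
    assert frame.n_water == 50
    d1 = np.linalg.norm(frame.h1 - frame.oxygens, axis=1)
    d2 = np.linalg.norm(frame.h2 - frame.oxygens, axis=1)
    assert np.allclose(d1, 0.1) and np.allclose(d2, 0.1)
    hh = np.linalg.norm(frame.h1 - frame.h2, axis=1)
    expected_hh = 2 * 0.1 * math.sin(math.radians(109.47 / 2))
    assert np.allclose(hh, expected_hh)

    cage = build_buckyball(FixtureRecipe(host="CAPO"))
    shifted = cage.with_positions(cage.positions + 1.25)
    frame2 = build_water_frame(40, 2.5, seed=3, solute=shifted)
    d = shifted.positions[:, None, :] - frame2.oxygens[None, :, :]
    d -= 2.5 * np.round(d / 2.5)
    assert np.linalg.norm(d, axis=-1).min() >= 0.24


def test_water_frame_radial_orientation():
    center = np.array([1.25, 1.25, 1.25])
    out_f = build_water_frame(30, 2.5, seed=7, orientation="radial_out", center=center)
    units = out_f.dipole_unit_vectors()
    radial = out_f.oxygens - center
    radial -= 2.5 * np.round(radial / 2.5)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert np.all(np.sum(units * radial, axis=1) > 0.55)
    in_f = build_water_frame(30, 2.5, seed=7, orientation="radial_in", center=center)
    units_in = in_f.dipole_unit_vectors()
    assert np.all(np.sum(units_in * radial, axis=1) < -0.55)
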