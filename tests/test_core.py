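import numpy as np
import pytest

from chargecorr.core import (
    DEFAULT_LAMBDAS,
    CorrectionLedger,
    LambdaSeries,
    SchemeSpec,
    SoluteAtom,
    SoluteStructure,
    validate_structure,
)


def atom(name="A", element="C", pos=(0, 0, 0), q=0.0, group="guest", **kw):
    return SoluteAtom(name=name, element=element, position=np.asarray(pos, float),
                      charge=q, group=group, **kw)


def test_atom_position_must_be_3vector():
    with pytest.raises(ValueError):
        SoluteAtom(name="X", element="C", position=np.zeros(2), charge=0.0)


def test_structure_accessors_and_net_charge():
    s = SoluteStructure([
        atom("N", "N", (0, 0, 0), -0.6, "guest"),
        atom("H1", "H", (0.1, 0, 0), 0.4, "guest", is_polar_hydrogen=True),
        atom("C1", "C", (1, 0, 0), 0.2, "host"),
    ])
    assert s.n_atoms == 3
    assert list(s.guest_indices) == [0, 1]
    assert list(s.host_indices) == [2]
    assert s.net_charge("guest") == pytest.approx(-0.2)
    assert s.net_charge() == pytest.approx(0.0)


def test_scaled_guest_charges_leave_host_untouched():
    s = SoluteStructure([atom(q=1.0), atom("C1", group="host", q=0.5)])
    half = s.with_scaled_guest_charges(0.5)
    assert half.charges[0] == pytest.approx(0.5)
    assert half.charges[1] == pytest.approx(0.5)
    assert s.charges[0] == pytest.approx(1.0)  # original unchanged


def test_with_positions_validates_shape():
    s = SoluteStructure([atom(), atom("B")])
    moved = s.with_positions(np.ones((2, 3)))
    assert np.allclose(moved.positions, 1.0)
    with pytest.raises(ValueError):
        s.with_positions(np.ones((3, 3)))


def test_guest_exclusion_pairs_filters_host_pairs():
    s = SoluteStructure(
        [atom(), atom("B"), atom("C1", group="host")],
        exclusions={frozenset((0, 1)), frozenset((1, 2))},
    )
    assert s.guest_exclusion_pairs() == [(0, 1)]


def test_validate_structure_flags_problems():
    good = SoluteStructure([
        atom("N", "N", (0, 0, 0), -0.6),
        atom("H1", "H", (0.1, 0, 0), 0.4, is_polar_hydrogen=True),
        atom("H2", "H", (0, 0.1, 0), 0.4, is_polar_hydrogen=True),
        atom("H3", "H", (0, 0, 0.1), 0.4, is_polar_hydrogen=True),
        atom("CH3", "CH3", (0, 0, -0.15), 0.4),
    ], label="MAM")
    assert validate_structure(good) == []

    bad = SoluteStructure([atom(q=0.5)], exclusions={frozenset((0, 5))},
                          label="MAM")
    msgs = validate_structure(bad)
    assert any("exclusion" in m for m in msgs)
    assert any("net charge" in m for m in msgs)


def test_scheme_spec_boundary_rules():
    assert SchemeSpec("CB", box_edge_L=3.0).boundary == "NPBC"
    assert SchemeSpec("LS", box_edge_L=3.0).boundary == "PBC"
    with pytest.raises(ValueError):
        SchemeSpec("LS", box_edge_L=-1.0)
    with pytest.raises(ValueError):
        SchemeSpec("BM", box_edge_L=1.0, cutoff_RC=1.4)


def test_lambda_series_validation():
    with pytest.raises(ValueError):
        LambdaSeries(np.array([0.0, 0.5]), np.zeros(2))  # must end at 1
    with pytest.raises(ValueError):
        LambdaSeries(np.array([0.0, 0.6, 0.4, 1.0]), np.zeros(4))  # not increasing
    with pytest.raises(ValueError):
        LambdaSeries(DEFAULT_LAMBDAS, np.zeros(5))  # length mismatch
    ok = LambdaSeries(DEFAULT_LAMBDAS, np.arange(11.0))
    assert ok.lambdas[0] == 0.0 and ok.lambdas[-1] == 1.0


def test_correction_ledger_identity_and_validation():
    led = CorrectionLedger(raw=1.0, dG_pol=2.0, dG_sum=3.0, dG_hs=0.0,
                           dG_excl=-0.5, corrected=5.5, environment="W")
    assert led.identity_residual() == pytest.approx(0.0)
    assert led.validate() == []
    bad = CorrectionLedger(raw=1.0, dG_pol=2.0, dG_sum=3.0, dG_hs=1.0,
                           dG_excl=0.0, corrected=10.0, environment="W")
    msgs = bad.validate()
    assert any("identity" in m for m in msgs)
    assert any("dG_hs" in m for m in msgs)
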