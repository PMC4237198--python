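import numpy as np
import pytest

from chargecorr.core import DEFAULT_LAMBDAS, CorrectionLedger, LambdaSeries
from chargecorr.report import (
    assemble_corrected,
    audit_ledgers,
    binding_contribution,
    combination_stats,
    consistency_rmsd,
    decompose,
    decomposition_from_components,
    round_report,
)


def test_round_report_half_away_from_zero():
    assert round_report(0.05) == 0.1
    assert round_report(-0.05) == -0.1
    assert round_report(2.34) == 2.3
    assert round_report(-2.35) == -2.4
    assert round_report(310.55) == 310.6
    assert round_report(1.25, decimals=1) == 1.3  # 1.25 is exact in binary


def test_assemble_corrected_identity_and_water_rule():
    led = assemble_corrected(-172.6, -75.9, -78.3, 0.0, 0.4,
                             guest="MAM", environment="W", scheme_tag="LS,ss")
    assert led.corrected == pytest.approx(led.components_sum(), abs=1e-12)
    assert led.validate() == []
    with pytest.raises(ValueError):
        assemble_corrected(-172.6, -75.9, -78.3, 1.0, 0.4, environment="W")
    # a charged host may carry a guest-host correction
    host = assemble_corrected(102.8, -146.4, -77.1, 102.6, -0.1,
                              guest="MAM", environment="CPOS", scheme_tag="LS,l")
    assert host.corrected == pytest.approx(-18.2, abs=1e-9)


def test_binding_contribution_differences_and_guest_check():
    w = assemble_corrected(-100.0, -5.0, -3.0, 0.0, 0.0, guest="MAM",
                           environment="W", scheme_tag="LS,ss")
    h = assemble_corrected(-40.0, -2.0, -1.0, 4.0, 0.0, guest="MAM",
                           environment="CNEG", scheme_tag="LS,l")
    rec = binding_contribution(w, h)
    assert rec.ddG_raw == pytest.approx(60.0)
    assert rec.ddG_cor == pytest.approx(h.corrected - w.corrected)
    assert rec.host == "CNEG"
    other = assemble_corrected(-40.0, 0.0, 0.0, 0.0, 0.0, guest="ACE",
                               environment="CNEG", scheme_tag="LS,l")
    with pytest.raises(ValueError):
        binding_contribution(w, other)


def test_consistency_rmsd_population_convention():
    assert consistency_rmsd([0.0, 2.0]) == pytest.approx(1.0)
    assert consistency_rmsd([3.0, 3.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        consistency_rmsd([1.0])


def _ledger(tag, corrected):
    return CorrectionLedger(raw=corrected, dG_pol=0.0, dG_sum=0.0, dG_hs=0.0,
                            dG_excl=0.0, corrected=corrected, guest="MAM",
                            environment="H", scheme_tag=tag)


def test_combination_stats_counts_and_union_identity():
    w_tags = ["LS,ss", "LS,s", "LS,l", "LS,xl", "BM,s", "BM,l"]
    h_tags = ["LS,ss", "LS,s", "LS,l", "LS,xl", "BM,s", "BM,l"]
    rng = np.random.default_rng(0)
    lw = {t: _ledger(t, float(v)) for t, v in zip(w_tags, rng.normal(-300, 2, 6))}
    lh = {t: _ledger(t, float(v)) for t, v in zip(h_tags, rng.normal(-100, 2, 6))}
    m_ls, _, n_ls = combination_stats(lw, lh, "LS")
    m_bm, _, n_bm = combination_stats(lw, lh, "BM")
    m_all, _, n_all = combination_stats(lw, lh, "LS+BM")
    assert (n_ls, n_bm, n_all) == (16, 4, 20)
    # the union mean is the count-weighted mean of the per-scheme means
    assert m_all == pytest.approx((16 * m_ls + 4 * m_bm) / 20, abs=1e-12)
    with pytest.raises(ValueError):
        combination_stats({t: lw[t] for t in w_tags[:4]},
                          {t: lh[t] for t in h_tags[:4]}, "BM")


def test_decompose_recovers_linear_cross_term():
    lam = DEFAULT_LAMBDAS
    guest = -50.0 + 10.0 * lam
    host = np.full_like(lam, -7.0)
    cross_slope = 24.0  # constant dU_cross/dlambda
    total = guest + host + cross_slope * lam
    led = assemble_corrected(-120.0, -5.0, -3.0, 4.0, 0.5,
                             guest="MAM", environment="CNEG")
    rec = decompose(LambdaSeries(lam, total), LambdaSeries(lam, guest),
                    LambdaSeries(lam, host), led)
    assert rec.raw_host == pytest.approx(cross_slope, abs=1e-9)
    assert rec.raw_solvent == pytest.approx(led.raw - cross_slope, abs=1e-9)
    assert rec.cor_host == pytest.approx(cross_slope + led.dG_hs, abs=1e-9)
    assert rec.cor_total == pytest.approx(led.components_sum(), abs=1e-9)
    # an uncharged host contributes nothing
    rec0 = decompose(LambdaSeries(lam, guest + host), LambdaSeries(lam, guest),
                     LambdaSeries(lam, host),
                     assemble_corrected(-120.0, -5.0, -3.0, 0.0, 0.5))
    assert rec0.raw_host == pytest.approx(0.0, abs=1e-12)


def test_decompose_requires_shared_lambda_grid():
    lam = DEFAULT_LAMBDAS
    other = np.linspace(0.0, 1.0, 6)
    led = assemble_corrected(-1.0, 0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        decompose(LambdaSeries(lam, np.zeros_like(lam)),
                  LambdaSeries(other, np.zeros_like(other)),
                  LambdaSeries(lam, np.zeros_like(lam)), led)


def test_decomposition_from_components_totals():
    led = assemble_corrected(68.6, -67.0, -77.2, 135.3, -0.2,
                             guest="ACE", environment="CNEG")
    rec = decomposition_from_components(-210.0, led)
    assert rec.raw_total == pytest.approx(led.raw, abs=1e-12)
    assert rec.cor_total == pytest.approx(led.components_sum(), abs=1e-12)


def test_audit_ledgers_flags_broken_identity():
    good = assemble_corrected(-10.0, 1.0, 2.0, 0.0, 0.0, environment="W")
    bad = CorrectionLedger(raw=-10.0, dG_pol=1.0, dG_sum=2.0, dG_hs=0.0,
                           dG_excl=0.0, corrected=-3.0, guest="MAM",
                           environment="W", scheme_tag="LS,ss")
    problems = audit_ledgers([good, bad])
    assert len(problems) == 1
    assert "additive identity" in problems[0]
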