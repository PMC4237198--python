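"""Thermodynamic-cycle assembly and consistency statistics.

The corrected charging free energy of a guest in a given environment is
the raw simulated value plus four methodology corrections,

    corrected = raw + dG_pol + dG_sum + dG_hs + dG_excl ,

and the charging contribution to the binding free energy is the
difference between the host-environment and pure-water values.  Because
each scheme/box combination carries its own artifacts, consistency is
quantified by the spread of corrected values across combinations: a
successful correction collapses raw spreads of several kJ/mol to a
fraction of that.

Root-mean-square deviations are computed about the mean with divisor N
(population convention); reported tables round to 0.1 kJ/mol with ties
away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .core import CorrectionLedger, LambdaSeries
from .ti import trapezoid_ti


@dataclass
class BindingRecord:
    """Charging contribution to binding for one (water, host) pairing."""

    guest: str
    host: str
    water_scheme_tag: str  # scheme + box of the pure-water leg, e.g. "LS,ss"
    host_scheme_tag: str
    ddG_raw: float  # kJ/mol
    ddG_cor: float  # kJ/mol


@dataclass
class DecompositionRecord:
    """Solvent/host split of a raw and corrected charging free energy."""

    raw_solvent: float
    raw_host: float
    cor_solvent: float
    cor_host: float

    @property
    def raw_total(self) -> float:
        return self.raw_solvent + self.raw_host

    @property
    def cor_total(self) -> float:
        return self.cor_solvent + self.cor_host


def round_report(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching printed table precision."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def assemble_corrected(
    raw: float,
    dG_pol: float,
    dG_sum: float,
    dG_hs: float,
    dG_excl: float,
    *,
    guest: str = "",
    environment: str = "",
    scheme_tag: str = "",
    n_water: int = 0,
    box_edge_L: float = 0.0,
) -> CorrectionLedger:
    """Assemble a correction ledger; corrected is the exact sum.

    Charging in pure water (environment ``W``) has no guest-host
    interaction leg, so a nonzero ``dG_hs`` is rejected there.
    """
    if environment == "W" and dG_hs != 0.0:
        raise ValueError("dG_hs must be zero when charging in pure water")
    corrected = raw + dG_pol + dG_sum + dG_hs + dG_excl
    return CorrectionLedger(
        raw=raw, dG_pol=dG_pol, dG_sum=dG_sum, dG_hs=dG_hs, dG_excl=dG_excl,
        corrected=corrected, guest=guest, environment=environment,
        scheme_tag=scheme_tag, n_water=n_water, box_edge_L=box_edge_L,
    )


def binding_contribution(ledger_W: CorrectionLedger,
                         ledger_H: CorrectionLedger) -> BindingRecord:
    """Charging contribution to binding: host-environment minus water."""
    if ledger_W.guest and ledger_H.guest and ledger_W.guest != ledger_H.guest:
        raise ValueError("binding contribution requires the same guest in both legs")
    return BindingRecord(
        guest=ledger_H.guest,
        host=ledger_H.environment,
        water_scheme_tag=ledger_W.scheme_tag,
        host_scheme_tag=ledger_H.scheme_tag,
        ddG_raw=ledger_H.raw - ledger_W.raw,
        ddG_cor=ledger_H.corrected - ledger_W.corrected,
    )


def consistency_rmsd(values: Sequence[float]) -> float:
    """Root-mean-square deviation about the mean, divisor N."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def combination_stats(
    ledgers_W: Mapping[str, CorrectionLedger],
    ledgers_H: Mapping[str, CorrectionLedger],
    scheme_set: Literal["LS", "BM", "LS+BM"],
) -> tuple[float, float, int]:
    """Mean and rmsd of the corrected binding contribution over all
    in-scheme (water-box, host-box) pairings.

    Ledger mappings are keyed by scheme tag (e.g. ``"LS,ss"``); a scheme
    never mixes with the other, so ``LS+BM`` is the union of the
    all-LS and all-BM pairings (e.g. 16 + 4 = 20 combinations for four
    LS and two BM box sizes).  Returns (mean, rmsd, n) with the
    population (divisor N) rmsd.
    """
    schemes = ("LS", "BM") if scheme_set == "LS+BM" else (scheme_set,)
    vals = []
    for scheme in schemes:
        w_tags = [t for t in ledgers_W if t.split(",")[0] == scheme]
        h_tags = [t for t in ledgers_H if t.split(",")[0] == scheme]
        for wt in w_tags:
            for ht in h_tags:
                vals.append(ledgers_H[ht].corrected - ledgers_W[wt].corrected)
    if not vals:
        raise ValueError(f"no {scheme_set} combinations available")
    v = np.asarray(vals)
    mean = float(v.mean())
    rmsd = float(np.sqrt(np.mean((v - mean) ** 2))) if v.size > 1 else 0.0
    return mean, rmsd, int(v.size)


def decompose(
    series_total: LambdaSeries,
    series_guest_only: LambdaSeries,
    series_host_only: LambdaSeries,
    ledger: CorrectionLedger,
) -> DecompositionRecord:
    """Split a charging free energy into solvent and host contributions.

    Inputs are per-charge-state mean electrostatic energies sampled from
    the same ensembles with (i) full guest and host charges, (ii) full
    guest and zeroed host charges, and (iii) zeroed guest and full host
    charges.  The guest-host cross energy at coupling lambda is
    lambda-linear, so its lambda-derivative is (total - guest-only -
    host-only)/lambda at each sampled state; at lambda = 0 the
    derivative is linearly extrapolated from the first two charged
    states.  The host contribution to the raw value is the trapezoidal
    integral of that derivative; the solvent contribution is the
    remainder.  Corrections attach to their physical origin: the
    guest-host interaction correction to the host part, the solvent
    polarization/summation/exclusion corrections to the solvent part.
    """
    lam = series_total.lambdas
    if not (np.array_equal(lam, series_guest_only.lambdas)
            and np.array_equal(lam, series_host_only.lambdas)):
        raise ValueError("the three series must share the same lambda grid")
    cross = series_total.values - series_guest_only.values - series_host_only.values
    deriv = np.empty_like(cross)
    nz = lam > 0
    deriv[nz] = cross[nz] / lam[nz]
    if not nz[0]:
        if nz.sum() >= 2:
            l1, l2 = lam[nz][:2]
            d1, d2 = deriv[nz][:2]
            deriv[0] = d1 - (d2 - d1) / (l2 - l1) * l1
        else:
            deriv[0] = deriv[nz][0]
    raw_host = trapezoid_ti(LambdaSeries(lam, deriv)).value
    raw_solvent = ledger.raw - raw_host
    cor_host = raw_host + ledger.dG_hs
    cor_solvent = raw_solvent + ledger.dG_pol + ledger.dG_sum + ledger.dG_excl
    return DecompositionRecord(raw_solvent=raw_solvent, raw_host=raw_host,
                               cor_solvent=cor_solvent, cor_host=cor_host)


def decomposition_from_components(raw_host: float,
                                  ledger: CorrectionLedger) -> DecompositionRecord:
    """Decomposition when the host cross contribution is already known
    (e.g. when replaying benchmark per-system host contributions)."""
    raw_solvent = ledger.raw - raw_host
    return DecompositionRecord(
        raw_solvent=raw_solvent,
        raw_host=raw_host,
        cor_solvent=raw_solvent + ledger.dG_pol + ledger.dG_sum + ledger.dG_excl,
        cor_host=raw_host + ledger.dG_hs,
    )


def audit_ledgers(ledgers: Iterable[CorrectionLedger],
                  tol: float = CorrectionLedger.IDENTITY_TOL_ROUNDED) -> list[str]:
    """Collect additive-identity violations across a set of ledgers."""
    problems: list[str] = []
    for led in ledgers:
        problems.extend(led.validate(tol))
    return problems
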