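"""Closed-form summation-scheme corrections.

Simulation codes accumulate the solvent-generated electrostatic
potential at solute atom sites atom-by-atom ("P-summation").  For a
solvent of neutral molecules with a nonvanishing quadrupole-moment
trace gamma_s (relative to the molecular van der Waals site), this
differs from the physically appropriate molecule-based summation by a
constant offset potential proportional to the density of solvent
molecules whose sites contribute.  The resulting spurious contribution
to the charging free energy is linear in the guest net charge Q_G and
is removed here.

For lattice summation the offset involves every water in the box,

    dG_sum(LS) = -Q_G * gamma_s * N_w / (6 eps0 L^3),

while for the cutoff-based Barker-Watts scheme only the waters inside
the cutoff sphere contribute, through the Laplacian of the reaction-
field part of the kernel (the quadrupole trace couples to nabla^2 psi,
which is 3 C_RF / R_C^3 inside the cutoff and zero for the shifted
Coulomb part),

    dG_sum(BM) = -Q_G * gamma_s * C_RF * <N_v> / (8 pi eps0 R_C^3),

with C_RF the Barker-Watts constant of the reaction-field permittivity.
Both population terms (box and cutoff sphere) carry configurable
weights so that alternative conventions can be reproduced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_FACTOR, GAMMA_S_SPC
from .pairpot import reaction_field_constant


@dataclass
class SummationParams:
    guest_net_charge: float  # e
    n_water: int = 0
    box_edge_L: float = 0.0  # nm
    gamma_s: float = GAMMA_S_SPC  # e nm^2
    cutoff_RC: float = 1.4  # nm (BM)
    n_in_cutoff: float | None = None  # <N_v> (BM)
    eps_reaction_field: float = 66.6  # (BM)

    def __post_init__(self) -> None:
        if self.gamma_s <= 0:
            raise ValueError("gamma_s must be positive")
        if self.n_in_cutoff is not None and not (0 <= self.n_in_cutoff <= max(self.n_water, self.n_in_cutoff)):
            raise ValueError("n_in_cutoff must be nonnegative")


def dG_sum_ls(p: SummationParams) -> float:
    """Summation correction for the lattice-summation scheme, kJ/mol.

    -Q_G gamma_s N_w / (6 eps0 L^3), negative for cations and positive
    for anions; nearly box-size independent at constant water density.
    """
    if p.box_edge_L <= 0:
        raise ValueError("box edge must be positive")
    inv_six_eps0 = 4.0 * math.pi * COULOMB_FACTOR / 6.0  # 1/(6 eps0), molar units
    return -p.guest_net_charge * p.gamma_s * inv_six_eps0 * p.n_water / p.box_edge_L**3


def dG_sum_bm(p: SummationParams, *, box_term_weight: float = 0.0,
              cutoff_term_weight: float = 1.0) -> float:
    """Summation correction for the Barker-Watts cutoff scheme, kJ/mol.

    The default combines only the cutoff-sphere population term (the
    reaction-field Laplacian acting on the <N_v> waters inside R_C); a
    box-population term identical in form to the LS expression can be
    mixed in through ``box_term_weight`` to emulate earlier conventions.
    """
    if p.n_in_cutoff is None:
        raise ValueError("n_in_cutoff (<N_v>) is required for the BM correction")
    crf = reaction_field_constant(p.eps_reaction_field)
    inv_six_eps0 = 4.0 * math.pi * COULOMB_FACTOR / 6.0
    # gamma_s/6 * nabla^2 psi_RF summed over N_v waters: 3 C_RF / (4 pi R_C^3)
    # per unit density, i.e. an effective density C_RF * 3 N_v / (4 pi R_C^3).
    rho_cut = 3.0 * p.n_in_cutoff / (4.0 * math.pi * p.cutoff_RC**3)
    val = -p.guest_net_charge * p.gamma_s * inv_six_eps0 * crf * rho_cut * cutoff_term_weight
    if box_term_weight != 0.0:
        if p.box_edge_L <= 0:
            raise ValueError("box edge must be positive for the box term")
        val += box_term_weight * (
            -p.guest_net_charge * p.gamma_s * inv_six_eps0 * p.n_water / p.box_edge_L**3
        )
    return val


def check_direct_term_negligible(guest_volume: float, box_volume: float,
                                 threshold: float = 0.05) -> bool:
    """Warn when the neglected direct-interaction term may matter.

    The remaining correction for direct periodic guest-guest
    interactions scales with the guest-to-box volume ratio and is
    neglected throughout this package; a warning is emitted when the
    ratio exceeds ``threshold``.
    """
    ratio = guest_volume / box_volume
    if ratio > threshold:
        warnings.warn(
            f"guest/box volume ratio {ratio:.3f} exceeds {threshold}; the neglected "
            "direct periodic guest-guest term may no longer be negligible",
            stacklevel=2,
        )
        return False
    return True


def estimate_n_in_cutoff(frames, center_rule: str, R_C: float) -> float:
    """Mean number of water oxygens within R_C of the chosen centre.

    ``center_rule`` is ``buckyball-COM`` (centre of mass of the 60 cage
    carbons of the frame's solute) or ``guest-charge-center`` (the MAM
    nitrogen / ACE carboxylate carbon, i.e. the first guest atom).
    Distances are minimum-image in the frame's cubic box.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames provided")
    counts = []
    for fr in frames:
        center = _resolve_center(fr, center_rule)
        d = fr.oxygens - center
        L = fr.box_edge_L
        d -= L * np.round(d / L)
        counts.append(int(np.sum(np.linalg.norm(d, axis=1) < R_C)))
    return float(np.mean(counts))


def _resolve_center(frame, center_rule: str) -> np.ndarray:
    s = frame.solute
    if center_rule == "buckyball-COM":
        if s is None:
            raise ValueError("frame has no solute to locate the cage centre")
        host = s.positions[s.host_indices]
        return host[:60].mean(axis=0)
    if center_rule == "guest-charge-center":
        if s is None:
            raise ValueError("frame has no solute to locate the guest centre")
        return s.positions[s.guest_indices[0]]
    raise ValueError(f"unknown center rule {center_rule!r}")
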