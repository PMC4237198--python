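"""Effective pairwise electrostatic interaction functions.

Three interaction kernels are provided, all returning a geometry factor
psi in nm^-1 so that the pair energy is ``COULOMB_FACTOR * q_i * q_j *
psi``:

* ``CB`` -- plain Coulomb, 1/r, for a macroscopic nonperiodic system;
* ``BM`` -- Barker-Watts reaction field with cutoff truncation, shifted
  so the potential vanishes continuously at the cutoff R_C;
* ``LS`` -- the periodic Coulomb Green's function of a cubic lattice
  (Ewald form with tinfoil boundary conditions and a neutralising
  background, i.e. zero box-average potential), without the self term.

On top of the kernels this module provides guest-environment energies
and the two pairwise correction terms: the guest-host interaction
correction (replacing effective-scheme guest-host electrostatics by
nonperiodic Coulomb ones) and the excluded-pair correction (removing
the non-Coulombic residue of the effective scheme acting between
covalently excluded guest atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_FACTOR
from .core import LambdaSeries, SchemeSpec, SoluteStructure
from .ti import trapezoid_ti

Kind = Literal["CB", "BM", "LS"]

#: Ewald splitting parameter as a multiple of 1/L.
EWALD_ALPHA_FACTOR = 3.5
#: Reciprocal-space shells: include integer triples with |n|^2 <= this.
EWALD_KMAX_SQ = 64
#: Real-space image shells (infinity norm).
EWALD_NMAX_REAL = 2


@dataclass
class EffectivePotential:
    """A kernel bound to its scheme parameters."""

    kind: Kind
    params: SchemeSpec
    ewald_alpha: float | None = None  # nm^-1, default EWALD_ALPHA_FACTOR / L
    kspace_cut: int = EWALD_KMAX_SQ
    self_term_included: bool = False  # the guest self term is never included

    def __call__(self, rvec: np.ndarray) -> float | np.ndarray:
        return psi(self.kind, rvec, self.params,
                   ewald_alpha=self.ewald_alpha, kmax_sq=self.kspace_cut)


def reaction_field_constant(eps_rf: float) -> float:
    """Barker-Watts constant C_RF at zero ionic strength."""
    return 2.0 * (eps_rf - 1.0) / (2.0 * eps_rf + 1.0)


@lru_cache(maxsize=32)
def _kvectors(L: float, kmax_sq: int) -> tuple[np.ndarray, np.ndarray]:
    nmax = int(math.isqrt(kmax_sq))
    rng = np.arange(-nmax, nmax + 1)
    n = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    n2 = np.sum(n * n, axis=1)
    keep = (n2 > 0) & (n2 <= kmax_sq)
    k = (2.0 * math.pi / L) * n[keep].astype(float)
    k2 = np.sum(k * k, axis=1)
    return k, k2


@lru_cache(maxsize=8)
def _image_shifts(L: float, nmax: int) -> np.ndarray:
    rng = np.arange(-nmax, nmax + 1)
    n = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    return L * n.astype(float)


def _psi_ls(rvec: np.ndarray, L: float, alpha: float, kmax_sq: int) -> np.ndarray:
    """Ewald evaluation of the periodic Coulomb Green's function (no self term)."""
    r = np.atleast_2d(np.asarray(rvec, dtype=float))
    shifts = _image_shifts(L, EWALD_NMAX_REAL)
    d = r[:, None, :] + shifts[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    if np.any(dist < 1e-12):
        raise ValueError("singular input: zero separation (self term excluded)")
    real = np.sum(erfc(alpha * dist) / dist, axis=1)
    k, k2 = _kvectors(L, kmax_sq)
    phase = r @ k.T  # (N, nk)
    recip = (4.0 * math.pi / L**3) * np.sum(
        np.exp(-k2 / (4.0 * alpha**2)) / k2 * np.cos(phase), axis=1
    )
    background = math.pi / (alpha**2 * L**3)
    out = real + recip - background
    return out if out.shape != (1,) else out


def _psi_bm(r: np.ndarray, rc: float, eps_rf: float) -> np.ndarray:
    crf = reaction_field_constant(eps_rf)
    inside = r < rc
    out = np.zeros_like(r)
    ri = r[inside]
    out[inside] = 1.0 / ri + crf * ri**2 / (2.0 * rc**3) - (1.0 + crf / 2.0) / rc
    return out


def psi(kind: Kind, rvec: np.ndarray, spec: SchemeSpec, *,
        ewald_alpha: float | None = None, kmax_sq: int = EWALD_KMAX_SQ):
    """Geometry factor of the pair interaction, nm^-1.

    ``rvec`` is a 3-vector or an (N, 3) array of pair vectors.  For BM
    the minimum-image vector should be passed (the kernel itself is not
    periodic); the LS kernel is L-periodic so any image works.
    """
    r = np.asarray(rvec, dtype=float)
    single = r.ndim == 1
    r2d = np.atleast_2d(r)
    dist = np.linalg.norm(r2d, axis=1)
    if kind != "LS" and np.any(dist < 1e-12):
        raise ValueError("singular input: zero separation")
    if kind == "CB":
        out = 1.0 / dist
    elif kind == "BM":
        out = _psi_bm(dist, spec.cutoff_RC, spec.eps_reaction_field)
    elif kind == "LS":
        alpha = ewald_alpha if ewald_alpha is not None else EWALD_ALPHA_FACTOR / spec.box_edge_L
        out = _psi_ls(r2d, spec.box_edge_L, alpha, kmax_sq)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return float(out[0]) if single else out


def psi_minus_coulomb(kind: Kind, rvec: np.ndarray, spec: SchemeSpec, *,
                      ewald_alpha: float | None = None,
                      kmax_sq: int = EWALD_KMAX_SQ):
    """psi(kind) - 1/r, which stays finite as r -> 0.

    The short-range Coulomb singularity of the effective kernels cancels
    against 1/r; for LS the r -> 0 limit is the cubic-lattice (Wigner)
    self potential, for BM it is the constant reaction-field shift.
    """
    r = np.asarray(rvec, dtype=float)
    single = r.ndim == 1
    r2d = np.atleast_2d(r)
    dist = np.linalg.norm(r2d, axis=1)
    if kind == "CB":
        out = np.zeros_like(dist)
    elif kind == "BM":
        crf = reaction_field_constant(spec.eps_reaction_field)
        rc = spec.cutoff_RC
        inside = dist < rc
        out = np.where(inside, crf * dist**2 / (2.0 * rc**3) - (1.0 + crf / 2.0) / rc, 0.0)
        # beyond the cutoff the full kernel is zero, so the residue is -1/r
        out[~inside] = -1.0 / dist[~inside]
    elif kind == "LS":
        L = spec.box_edge_L
        alpha = ewald_alpha if ewald_alpha is not None else EWALD_ALPHA_FACTOR / L
        shifts = _image_shifts(L, EWALD_NMAX_REAL)
        d = r2d[:, None, :] + shifts[None, :, :]
        dd = np.linalg.norm(d, axis=-1)
        central = np.argmin(np.abs(shifts).sum(axis=1))
        # erf(alpha r)/r is analytic at r = 0 (limit 2 alpha / sqrt(pi))
        r0 = dd[:, central]
        with np.errstate(divide="ignore", invalid="ignore"):
            smooth = np.where(r0 < 1e-8,
                              2.0 * alpha / math.sqrt(math.pi)
                              - 2.0 * alpha**3 * r0**2 / (3.0 * math.sqrt(math.pi)),
                              (1.0 - erfc(alpha * r0)) / r0)
        mask = np.ones(len(shifts), dtype=bool)
        mask[central] = False
        real_images = np.sum(erfc(alpha * dd[:, mask]) / dd[:, mask], axis=1)
        k, k2 = _kvectors(L, kmax_sq)
        recip = (4.0 * math.pi / L**3) * np.sum(
            np.exp(-k2 / (4.0 * alpha**2)) / k2 * np.cos(r2d @ k.T), axis=1
        )
        out = -smooth + real_images + recip - math.pi / (alpha**2 * L**3)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return float(out[0]) if single else out


def wigner_self_potential(L: float) -> float:
    """r -> 0 limit of psi_LS - 1/r: the cubic-lattice self potential, nm^-1."""
    return float(psi_minus_coulomb("LS", np.zeros(3), SchemeSpec("LS", box_edge_L=L)))


# ---------------------------------------------------------------------------
# guest-environment energies and pairwise corrections
# ---------------------------------------------------------------------------

def _minimum_image(vecs: np.ndarray, L: float) -> np.ndarray:
    return vecs - L * np.round(vecs / L)


def guest_env_energy(
    s: SoluteStructure,
    lam: float,
    kind: Kind,
    spec: SchemeSpec,
    partition: Literal["host", "all-nonguest"] = "host",
    ewald_alpha: float | None = None,
    kmax_sq: int = EWALD_KMAX_SQ,
) -> float:
    """Electrostatic guest-environment energy, kJ/mol.

    Sums COULOMB_FACTOR * (lam q_i) * q_j * psi over guest atoms i and
    environment atoms j; guest-guest (intramolecular) pairs are excluded
    entirely.  BM and LS pair vectors are minimum-imaged; CB uses the
    plain in-box vectors (nonperiodic system).
    """
    gi = s.guest_indices
    ei = s.host_indices if partition == "host" else s.indices("host")
    if gi.size == 0 or ei.size == 0:
        return 0.0
    pos, q = s.positions, s.charges
    vecs = (pos[gi][:, None, :] - pos[ei][None, :, :]).reshape(-1, 3)
    if kind in ("BM", "LS"):
        vecs = _minimum_image(vecs, spec.box_edge_L)
    dist = np.linalg.norm(vecs, axis=1)
    if np.any(dist < 1e-6):
        raise ValueError("singular input: overlapping guest/environment atoms")
    psis = psi(kind, vecs, spec, ewald_alpha=ewald_alpha, kmax_sq=kmax_sq)
    qq = (q[gi][:, None] * q[ei][None, :]).ravel()
    return float(COULOMB_FACTOR * lam * np.sum(qq * psis))


def _per_lambda_mean_dUdlam(series: LambdaSeries, kind: Kind, spec: SchemeSpec,
                            ewald_alpha: float | None = None,
                            kmax_sq: int = EWALD_KMAX_SQ) -> np.ndarray:
    """Per-lambda ensemble averages of dU_GH/dlambda.

    U_GH(lambda) is linear in lambda (all guest charges scale together),
    so dU/dlambda equals the full-charge guest-host energy of each
    configuration.
    """
    if series.configs is None:
        raise ValueError("lambda series carries no configuration sets")
    means = []
    for entry in series.configs:
        frames = entry if isinstance(entry, (list, tuple)) else [entry]
        vals = [guest_env_energy(f, 1.0, kind, spec, partition="host",
                                 ewald_alpha=ewald_alpha, kmax_sq=kmax_sq) for f in frames]
        means.append(float(np.mean(vals)))
    return np.asarray(means)


def dG_hs(series: LambdaSeries, kind_eff: Kind, spec: SchemeSpec,
          ewald_alpha: float | None = None,
          kmax_sq: int = EWALD_KMAX_SQ) -> float:
    """Guest-host interaction correction, kJ/mol.

    Difference of two TI estimates of the guest-host charging free
    energy: Coulombic/nonperiodic minus effective-scheme/periodic, each
    a trapezoidal integral of per-lambda averages of dU_GH/dlambda over
    the sampled configurations.  Zero when the host carries no charges.
    """
    if kind_eff not in ("LS", "BM"):
        raise ValueError("effective scheme must be LS or BM")
    cb_spec = SchemeSpec("CB", box_edge_L=spec.box_edge_L,
                         eps_experimental=spec.eps_experimental)
    means_cb = _per_lambda_mean_dUdlam(series, "CB", cb_spec)
    means_eff = _per_lambda_mean_dUdlam(series, kind_eff, spec,
                                        ewald_alpha=ewald_alpha, kmax_sq=kmax_sq)
    ti_cb = trapezoid_ti(LambdaSeries(series.lambdas, means_cb)).value
    ti_eff = trapezoid_ti(LambdaSeries(series.lambdas, means_eff)).value
    return ti_cb - ti_eff


def dG_excl(s: SoluteStructure, kind_eff: Kind, spec: SchemeSpec) -> float:
    """Excluded-pair correction, kJ/mol.

    Excluded guest atom pairs interact in the simulation through the
    non-Coulombic residue psi_eff - 1/r of the effective kernel.  Both
    charges of a pair scale with lambda, so the TI integral over the
    quadratic lambda-dependence evaluates analytically to the
    full-charge pair energy, which is removed (negated).  Zero for
    monoatomic guests or empty exclusion lists.
    """
    pairs = s.guest_exclusion_pairs()
    if not pairs:
        return 0.0
    pos, q = s.positions, s.charges
    vecs = np.array([pos[i] - pos[j] for i, j in pairs])
    vecs = _minimum_image(vecs, spec.box_edge_L)
    resid = psi_minus_coulomb(kind_eff, vecs, spec)
    qq = np.array([q[i] * q[j] for i, j in pairs])
    return float(-COULOMB_FACTOR * np.sum(qq * resid))
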