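"""Domain types shared by all modules.

A :class:`SoluteStructure` holds the guest/host atoms (positions in nm,
partial charges in e, cavity radii in nm) together with bonds and the
electrostatic exclusion list (first and second covalent neighbours).
A :class:`SchemeSpec` describes the electrostatics methodology of a
simulation (lattice summation, reaction-field cutoff or plain Coulomb),
a :class:`LambdaSeries` the per-charge-state Hamiltonian-derivative
averages entering thermodynamic integration, and a
:class:`CorrectionLedger` the bookkeeping of one corrected charging
free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

GUEST_NET_CHARGE = {"MAM": 1.0, "ACE": -1.0}
HOST_NET_CHARGE = {"CAPO": 0.0, "CHB": 0.0, "CPOS": 1.0, "CNEG": -1.0}


@dataclass
class SoluteAtom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), nm
    charge: float  # e
    radius: float = 0.0  # nm, dielectric-cavity radius
    is_polar_hydrogen: bool = False
    group: Literal["guest", "host"] = "guest"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")


@dataclass
class SoluteStructure:
    """Atoms plus covalent topology of a guest, a host, or a complex."""

    atoms: list[SoluteAtom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    exclusions: set[frozenset[int]] = field(default_factory=set)
    label: str = ""

    # -- convenience accessors -------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def indices(self, group: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.group == group], dtype=int)

    @property
    def guest_indices(self) -> np.ndarray:
        return self.indices("guest")

    @property
    def host_indices(self) -> np.ndarray:
        return self.indices("host")

    def net_charge(self, group: Optional[str] = None) -> float:
        if group is None:
            return float(self.charges.sum())
        idx = self.indices(group)
        return float(self.charges[idx].sum()) if idx.size else 0.0

    def guest_exclusion_pairs(self) -> list[tuple[int, int]]:
        """Excluded pairs with both members in the guest, sorted."""
        guest = set(self.guest_indices.tolist())
        pairs = []
        for pair in self.exclusions:
            i, j = sorted(pair)
            if i in guest and j in guest:
                pairs.append((i, j))
        return sorted(pairs)

    def with_positions(self, positions: np.ndarray) -> "SoluteStructure":
        """Return a copy with atom positions replaced."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions must be (n_atoms, 3)")
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, positions)]
        return SoluteStructure(atoms, list(self.bonds), set(self.exclusions), self.label)

    def with_scaled_guest_charges(self, lam: float) -> "SoluteStructure":
        """Return a copy with guest partial charges scaled by lambda."""
        atoms = [
            replace(a, charge=a.charge * lam, position=a.position.copy())
            if a.group == "guest"
            else replace(a, position=a.position.copy())
            for a in self.atoms
        ]
        return SoluteStructure(atoms, list(self.bonds), set(self.exclusions), self.label)


def validate_structure(s: SoluteStructure) -> list[str]:
    """Check the structural invariants; return human-readable violations.

    An empty list means the structure is valid.  Checks: positive radii,
    finite positions, exclusion indices in range and no self-pairs, and
    (when the label identifies the guest) the guest net charge.
    """
    violations: list[str] = []
    n = s.n_atoms
    for i, a in enumerate(s.atoms):
        if a.radius < 0:
            violations.append(f"atom {i} ({a.name}): negative radius {a.radius}")
        if not np.all(np.isfinite(a.position)):
            violations.append(f"atom {i} ({a.name}): non-finite position")
    for pair in s.exclusions:
        idx = sorted(pair)
        if len(idx) == 1:
            violations.append(f"exclusion self-pair ({idx[0]},{idx[0]})")
            continue
        i, j = idx
        if not (0 <= i < n and 0 <= j < n):
            violations.append(f"exclusion pair ({i},{j}) out of range for {n} atoms")
    guest_label = _guest_label(s.label)
    if guest_label in GUEST_NET_CHARGE:
        q = s.net_charge("guest") if s.guest_indices.size else s.net_charge()
        q_ref = GUEST_NET_CHARGE[guest_label]
        if abs(q - q_ref) > 1e-10:
            violations.append(
                f"guest net charge {q:+.6f} differs from {q_ref:+.1f} expected for {guest_label}"
            )
    return violations


def _guest_label(label: str) -> str:
    if label.startswith("complex:"):
        return label.split(":", 1)[1].split("-")[0]
    return label


@dataclass
class SchemeSpec:
    """Electrostatics methodology of one simulation or continuum solve.

    ``scheme`` is LS (lattice summation under periodic boundary
    conditions), BM (Barker-Watts reaction field with cutoff), or CB
    (plain Coulomb in a nonperiodic macroscopic system).
    """

    scheme: Literal["LS", "BM", "CB"]
    box_edge_L: float  # nm
    n_water: int = 0
    cutoff_RC: float = 1.4  # nm, BM only
    eps_solvent_model: float = 66.6
    eps_reaction_field: float = 66.6
    eps_experimental: float = 78.4
    boundary: Literal["PBC", "NPBC"] = "PBC"

    def __post_init__(self) -> None:
        if self.scheme == "CB":
            self.boundary = "NPBC"
        elif self.scheme == "LS":
            self.boundary = "PBC"
        if self.box_edge_L <= 0:
            raise ValueError("box edge must be positive")
        if self.scheme == "BM" and not (0 < self.cutoff_RC < self.box_edge_L):
            raise ValueError("cutoff must satisfy 0 < R_C < L")


@dataclass
class LambdaSeries:
    """Per-charge-state ensemble averages <dH/dlambda> for TI."""

    lambdas: np.ndarray
    values: np.ndarray  # kJ/mol
    errors: Optional[np.ndarray] = None  # kJ/mol
    configs: Optional[list[SoluteStructure]] = None  # one snapshot set per lambda

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lambdas.ndim != 1 or len(self.lambdas) < 2:
            raise ValueError("need at least two lambda points")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        if not (math.isclose(self.lambdas[0], 0.0) and math.isclose(self.lambdas[-1], 1.0)):
            raise ValueError("lambda grid must start at 0 and end at 1")
        if self.values.shape != self.lambdas.shape:
            raise ValueError("values must match lambdas in length")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.lambdas.shape:
                raise ValueError("errors must match lambdas in length")


DEFAULT_LAMBDAS = np.linspace(0.0, 1.0, 11)


@dataclass
class CorrectionLedger:
    """Raw charging free energy, the four corrections, and their sum.

    The additive identity ``corrected = raw + dG_pol + dG_sum + dG_hs +
    dG_excl`` is enforced on construction; the host-interaction term is
    zero by definition for charging in pure water and for hosts without
    partial charges.
    """

    raw: float
    dG_pol: float
    dG_sum: float
    dG_hs: float
    dG_excl: float
    corrected: float
    guest: str = ""
    environment: str = ""  # "W" or a host label
    scheme_tag: str = ""  # e.g. "LS,ss"
    n_water: int = 0
    box_edge_L: float = 0.0

    IDENTITY_TOL_EXACT = 1e-9
    IDENTITY_TOL_ROUNDED = 0.15  # for tables printed to 0.1 kJ/mol

    def components_sum(self) -> float:
        return self.raw + self.dG_pol + self.dG_sum + self.dG_hs + self.dG_excl

    def identity_residual(self) -> float:
        return self.corrected - self.components_sum()

    def validate(self, tol: float = IDENTITY_TOL_ROUNDED) -> list[str]:
        violations = []
        resid = self.identity_residual()
        if abs(resid) > tol:
            violations.append(
                f"{self.guest}/{self.environment}/{self.scheme_tag}: additive identity "
                f"violated by {resid:+.3f} kJ/mol"
            )
        if self.environment in ("W", "CAPO") and self.dG_hs != 0.0:
            violations.append(
                f"{self.guest}/{self.environment}/{self.scheme_tag}: dG_hs must be zero "
                "for charging in water or in an uncharged host"
            )
        return violations
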