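"""Deterministic synthetic builders for the model guest-host systems.

The hosts are artificial C60 cages (truncated icosahedra) with every
C-C bond stretched to 0.2 nm, either bare and apolar (CAPO) or carrying
a covalently attached functional group: a neutral polar formamide
(CHB), a positively charged methylammonium (CPOS) or a negatively
charged formate (CNEG).  The guests are a methylammonium cation (MAM)
and an acetate anion (ACE).  Partial charges are the package defaults
from :mod:`chargecorr.constants`; geometries use idealised bond lengths
and angles.  All builders are pure functions of their recipe and seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .core import DEFAULT_LAMBDAS, LambdaSeries, SoluteAtom, SoluteStructure

GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0

HOSTS = ("CAPO", "CHB", "CPOS", "CNEG")
GUESTS = ("MAM", "ACE")


@dataclass(frozen=True)
class FixtureRecipe:
    host: str = "CAPO"
    guest: str = "none"
    bond_length: float = 0.2  # nm, the stretched C-C bond of the cage
    seed: int = 0
    jitter_sigma: float = 0.0  # nm, rigid-body jitter of the guest placement

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be nonnegative")


# ---------------------------------------------------------------------------
# cage geometry
# ---------------------------------------------------------------------------

def _truncated_icosahedron_vertices() -> np.ndarray:
    """The 60 vertices, edge length 2, centred at the origin."""
    phi = GOLDEN
    base = [
        (0.0, 1.0, 3.0 * phi),
        (1.0, 2.0 + phi, 2.0 * phi),
        (phi, 2.0, 2.0 * phi + 1.0),
    ]
    verts = set()
    for x, y, z in base:
        for cyc in ((x, y, z), (y, z, x), (z, x, y)):
            for sx in (1, -1):
                for sy in (1, -1):
                    for sz in (1, -1):
                        v = (sx * cyc[0], sy * cyc[1], sz * cyc[2])
                        verts.add(tuple(round(t, 10) for t in v))
    arr = np.array(sorted(verts), dtype=float)
    assert arr.shape == (60, 3)
    return arr


def _cage_bonds(verts: np.ndarray, edge: float) -> list[tuple[int, int]]:
    bonds = []
    for i, j in itertools.combinations(range(len(verts)), 2):
        if abs(np.linalg.norm(verts[i] - verts[j]) - edge) < 1e-6 * edge:
            bonds.append((i, j))
    return bonds


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _functional_group(host: str, anchor: np.ndarray, u: np.ndarray) -> list[SoluteAtom]:
    """Atoms of the cage functionalization, attached outward along ``u``."""
    v = _perpendicular(u)
    w = np.cross(u, v)

    def atom(name, element, pos, q, polar_h=False):
        return SoluteAtom(name, element, np.asarray(pos), q, group="host",
                          is_polar_hydrogen=polar_h)

    if host == "CHB":  # formamide -C(=O)-NH2
        q = c.CHB_GROUP_CHARGES
        C = anchor + 0.150 * u
        O = C + 0.123 * (0.5 * u + 0.866 * v)
        N = C + 0.133 * (0.5 * u - 0.866 * v)
        H1 = N + 0.100 * (0.8 * u - 0.6 * v)
        H2 = N + 0.100 * (-0.2 * u - 0.8 * v + 0.57 * w)
        return [
            atom("CG", "C", C, q["C"]),
            atom("OG", "O", O, q["O"]),
            atom("NG", "N", N, q["N"]),
            atom("HG1", "H", H1, q["H1"], True),
            atom("HG2", "H", H2, q["H2"], True),
        ]
    if host == "CPOS":  # methylammonium-like -NH3+
        q = c.CPOS_GROUP_CHARGES
        N = anchor + 0.147 * u
        hs = []
        for k, name in enumerate(("HG1", "HG2", "HG3")):
            ang = 2.0 * math.pi * k / 3.0
            d = _unit(0.40 * u + math.cos(ang) * v + math.sin(ang) * w)
            hs.append(atom(name, "H", N + 0.100 * d, q[f"H{k+1}"], True))
        return [atom("NG", "N", N, q["N"])] + hs
    if host == "CNEG":  # formate-like -COO-
        q = c.CNEG_GROUP_CHARGES
        C = anchor + 0.150 * u
        O1 = C + 0.125 * (0.5 * u + 0.866 * v)
        O2 = C + 0.125 * (0.5 * u - 0.866 * v)
        return [
            atom("CG", "C", C, q["C"]),
            atom("OG1", "O", O1, q["O1"]),
            atom("OG2", "O", O2, q["O2"]),
        ]
    raise ValueError(f"unknown host label {host!r}")


def build_buckyball(recipe: FixtureRecipe) -> SoluteStructure:
    """Build the (possibly functionalized) C60 cage host.

    The 60 carbons sit on a truncated-icosahedron hull scaled so that
    every bonded C-C distance equals ``recipe.bond_length``; the cage
    carbons carry zero partial charge.
    """
    if recipe.host not in HOSTS:
        raise ValueError(f"unknown host label {recipe.host!r}")
    verts = _truncated_icosahedron_vertices() * (recipe.bond_length / 2.0)
    atoms = [
        SoluteAtom(f"C{i+1}", "C", verts[i], 0.0, group="host") for i in range(60)
    ]
    bonds = _cage_bonds(verts, recipe.bond_length)
    assert len(bonds) == 90
    structure = SoluteStructure(atoms, bonds, set(), label=recipe.host)
    if recipe.host != "CAPO":
        # attach the group to the outermost +z vertex, pointing outward
        anchor_idx = int(np.argmax(verts[:, 2]))
        anchor = verts[anchor_idx]
        u = _unit(anchor)
        group = _functional_group(recipe.host, anchor, u)
        first_group_idx = len(structure.atoms)
        structure.atoms.extend(group)
        structure.bonds.append((anchor_idx, first_group_idx))
        for k in range(1, len(group)):
            structure.bonds.append((first_group_idx, first_group_idx + k))
    return structure


# ---------------------------------------------------------------------------
# guests
# ---------------------------------------------------------------------------

def _tetra_dirs(axis: np.ndarray) -> list[np.ndarray]:
    """Three unit vectors tetrahedrally arranged about ``-axis``."""
    v = _perpendicular(axis)
    w = np.cross(axis, v)
    dirs = []
    cos_t, sin_t = -1.0 / 3.0, math.sqrt(8.0) / 3.0
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        dirs.append(cos_t * axis + sin_t * (math.cos(ang) * v + math.sin(ang) * w))
    return dirs


def build_guest(guest: str) -> SoluteStructure:
    """Build a guest ion with its charge-bearing centre at the origin."""
    z = np.array([0.0, 0.0, 1.0])
    if guest == "MAM":
        q = c.MAM_CHARGES
        atoms = [
            SoluteAtom("N", "N", np.zeros(3), q["N"], group="guest"),
            SoluteAtom("CH3", "CH3", 0.147 * z, q["CH3"], group="guest"),
        ]
        for k, d in enumerate(_tetra_dirs(z)):
            atoms.append(SoluteAtom(f"H{k+1}", "H", 0.100 * d, q[f"H{k+1}"],
                                    is_polar_hydrogen=True, group="guest"))
        bonds = [(0, 1), (0, 2), (0, 3), (0, 4)]
        label = "MAM"
    elif guest == "ACE":
        q = c.ACE_CHARGES
        v = np.array([1.0, 0.0, 0.0])
        atoms = [
            SoluteAtom("C", "C", np.zeros(3), q["C"], group="guest"),
            SoluteAtom("CH3", "CH3", 0.153 * z, q["CH3"], group="guest"),
            SoluteAtom("O1", "O", 0.125 * (-0.5 * z + 0.866 * v), q["O1"], group="guest"),
            SoluteAtom("O2", "O", 0.125 * (-0.5 * z - 0.866 * v), q["O2"], group="guest"),
        ]
        bonds = [(0, 1), (0, 2), (0, 3)]
        label = "ACE"
    else:
        raise ValueError(f"unknown guest label {guest!r}")
    s = SoluteStructure(atoms, bonds, set(), label=label)
    s.exclusions = complete_exclusions(s)
    return s


def complete_exclusions(s: SoluteStructure) -> set[frozenset[int]]:
    """First (1-2) and second (1-3) covalent neighbour pairs."""
    neigh: dict[int, set[int]] = {i: set() for i in range(s.n_atoms)}
    for i, j in s.bonds:
        neigh[i].add(j)
        neigh[j].add(i)
    excl: set[frozenset[int]] = set()
    for i in range(s.n_atoms):
        for j in neigh[i]:
            if i < j:
                excl.add(frozenset((i, j)))
            for k in neigh[j]:
                if k != i and i < k:
                    excl.add(frozenset((i, k)))
    return excl


def build_complex(recipe: FixtureRecipe) -> SoluteStructure:
    """Place the guest at the cage centre of mass and merge the topologies.

    The guest's charge-bearing centre (MAM nitrogen / ACE carboxylate
    carbon, which builds at the origin) coincides with the cage centre
    of mass; a nonzero ``jitter_sigma`` adds a rigid Gaussian offset.
    Raises if any guest-host pair comes closer than 0.12 nm.
    """
    if recipe.guest not in GUESTS:
        raise ValueError("recipe.guest must be set to build a complex")
    host = build_buckyball(recipe)
    guest = build_guest(recipe.guest)
    cage_com = np.mean([a.position for a in host.atoms[:60]], axis=0)

    rng = np.random.default_rng(recipe.seed)
    offset = cage_com
    if recipe.jitter_sigma > 0:
        offset = offset + rng.normal(0.0, recipe.jitter_sigma, size=3)

    n_guest = guest.n_atoms
    atoms = [SoluteAtom(a.name, a.element, a.position + offset, a.charge,
                        a.radius, a.is_polar_hydrogen, "guest") for a in guest.atoms]
    atoms += host.atoms
    bonds = list(guest.bonds) + [(i + n_guest, j + n_guest) for i, j in host.bonds]
    excl = set(guest.exclusions) | {
        frozenset(i + n_guest for i in pair) for pair in complete_exclusions(host)
    }
    s = SoluteStructure(atoms, bonds, excl, label=f"complex:{recipe.guest}-{recipe.host}")

    gpos = s.positions[s.guest_indices]
    hpos = s.positions[s.host_indices]
    dmin = np.min(np.linalg.norm(gpos[:, None, :] - hpos[None, :, :], axis=-1))
    if dmin < 0.12:
        raise ValueError(
            f"steric placement impossible: guest-host contact {dmin:.3f} nm < 0.12 nm"
        )
    return s


# ---------------------------------------------------------------------------
# synthetic lambda-series
# ---------------------------------------------------------------------------

def synth_lambda_series(
    target_dG: float,
    curvature: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
) -> LambdaSeries:
    """Quadratic-in-lambda derivative profile with a prescribed TI result.

    Before noise, the trapezoidal integral of the returned values on the
    given grid equals ``target_dG`` exactly; ``curvature`` bends the
    profile without changing that integral.  Gaussian noise of standard
    deviation ``noise_sigma`` is then added per point (seeded).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    lam = DEFAULT_LAMBDAS.copy() if lambdas is None else np.asarray(lambdas, dtype=float)
    # trapezoid weights of the grid
    w = np.zeros_like(lam)
    dl = np.diff(lam)
    w[:-1] += dl / 2.0
    w[1:] += dl / 2.0
    quad = lam**2
    quad_centered = quad - np.dot(w, quad) / np.dot(w, np.ones_like(lam))
    values = target_dG * np.ones_like(lam) + curvature * quad_centered
    errors = None
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=lam.shape)
        errors = np.full_like(lam, noise_sigma)
    return LambdaSeries(lam, values, errors=errors)


# ---------------------------------------------------------------------------
# synthetic solvent configurations
# ---------------------------------------------------------------------------

@dataclass
class WaterFrame:
    """Rigid three-site water coordinates of one configuration (nm)."""

    oxygens: np.ndarray  # (N, 3)
    h1: np.ndarray  # (N, 3)
    h2: np.ndarray  # (N, 3)
    box_edge_L: float
    solute: SoluteStructure | None = None

    @property
    def n_water(self) -> int:
        return len(self.oxygens)

    def dipole_unit_vectors(self) -> np.ndarray:
        """Unit vectors along each water's molecular dipole (O -> H bisector)."""
        d = 0.5 * (self.h1 + self.h2) - self.oxygens
        return d / np.linalg.norm(d, axis=1, keepdims=True)


def _spc_sites(o: np.ndarray, dipole_dir: np.ndarray, azimuth: float) -> tuple[np.ndarray, np.ndarray]:
    u = _unit(dipole_dir)
    v = _perpendicular(u)
    w = np.cross(u, v)
    p = math.cos(azimuth) * v + math.sin(azimuth) * w
    half = math.radians(c.SPC_HOH_DEG / 2.0)
    h1 = o + c.SPC_OH * (math.cos(half) * u + math.sin(half) * p)
    h2 = o + c.SPC_OH * (math.cos(half) * u - math.sin(half) * p)
    return h1, h2


def build_water_frame(
    n_water: int,
    box_edge_L: float,
    seed: int = 0,
    orientation: str = "random",
    center: np.ndarray | None = None,
    solute: SoluteStructure | None = None,
    min_dist: float = 0.24,
    max_tries: int = 200,
) -> WaterFrame:
    """Random SPC-geometry water configuration in a cubic box.

    ``orientation`` is ``random``, ``radial_out`` (dipoles pointing away
    from ``center``) or ``radial_in``.  Oxygen positions are uniform in
    the box, rejected if closer than ``min_dist`` to a solute atom.
    """
    rng = np.random.default_rng(seed)
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    spos = solute.positions if solute is not None else None
    oxy = []
    tries = 0
    while len(oxy) < n_water:
        tries += 1
        if tries > max_tries * n_water:
            raise ValueError("could not place waters without solute overlap")
        p = rng.uniform(0.0, box_edge_L, size=3)
        if spos is not None:
            d = spos - p
            d -= box_edge_L * np.round(d / box_edge_L)
            if np.min(np.linalg.norm(d, axis=1)) < min_dist:
                continue
        oxy.append(p)
    oxy = np.array(oxy).reshape(n_water, 3)
    h1s, h2s = [], []
    for o in oxy:
        if orientation == "random":
            d = rng.normal(size=3)
        else:
            d = o - center
            d -= box_edge_L * np.round(d / box_edge_L)
            if np.linalg.norm(d) < 1e-12:
                d = rng.normal(size=3)
            if orientation == "radial_in":
                d = -d
        h1, h2 = _spc_sites(o, d, rng.uniform(0.0, 2.0 * math.pi))
        h1s.append(h1)
        h2s.append(h2)
    return WaterFrame(oxy, np.array(h1s), np.array(h2s), box_edge_L, solute=solute)
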