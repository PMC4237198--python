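"""Readers and writers for structures, topologies, ledgers, and configs.

Coordinate files are PDB (angstrom on disk, converted to nm in memory)
or GRO (nm).  Electrostatic metadata that neither format carries --
partial charges, cavity radii, polar-hydrogen flags, guest/host group
tags, bonds and exclusion pairs -- lives in a plain-text ``.chgtop``
sidecar of our own.  Atom indices are 0-based in memory and 1-based in
files.  Correction ledgers are exchanged as CSV with the fixed header
``guest,environment,scheme,box,Nw,L,raw,dG_pol,dG_sum,dG_hs,dG_excl,corrected``;
the additive identity is revalidated on read (0.15 kJ/mol tolerance for
values rounded to 0.1).  Benchmark tables of reference charging free
energies ship as package data and load through the ``load_benchmark_*``
helpers.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import CorrectionLedger, SoluteAtom, SoluteStructure

LEDGER_HEADER = ["guest", "environment", "scheme", "box", "Nw", "L",
                 "raw", "dG_pol", "dG_sum", "dG_hs", "dG_excl", "corrected"]


class ParseError(ValueError):
    """Malformed file content, annotated with the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# coordinate formats
# ---------------------------------------------------------------------------

def write_pdb(s: SoluteStructure, path) -> None:
    lines = []
    for i, a in enumerate(s.atoms):
        x, y, z = a.position * 10.0  # nm -> angstrom
        resname = "GST" if a.group == "guest" else "HST"
        lines.append(
            f"ATOM  {i + 1:5d} {a.name[:4]:<4s} {resname:<3s} A{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{a.element[:2]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Names, positions (nm) and element guesses from a PDB file."""
    names, positions, elements = [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            names.append(line[12:16].strip())
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, f"bad ATOM record: {exc}") from None
        positions.append([c / 10.0 for c in xyz])  # angstrom -> nm
        elements.append(line[76:78].strip() or names[-1][:1])
    return names, np.asarray(positions, dtype=float).reshape(-1, 3), elements


def write_gro(s: SoluteStructure, path, box_edge_L: float = 0.0) -> None:
    lines = [s.label or "structure", f"{len(s.atoms):5d}"]
    for i, a in enumerate(s.atoms):
        resname = "GST" if a.group == "guest" else "HST"
        x, y, z = a.position
        lines.append(f"{1:5d}{resname:<5s}{a.name[:5]:>5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box_edge_L:10.5f}{box_edge_L:10.5f}{box_edge_L:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path) -> tuple[list[str], np.ndarray, float]:
    """Names, positions (nm) and cubic box edge from a single-frame GRO."""
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise ParseError(path, 1, "GRO file needs title, count, and box lines")
    try:
        n = int(text[1].strip())
    except ValueError:
        raise ParseError(path, 2, f"bad atom count {text[1]!r}") from None
    if len(text) < n + 3:
        raise ParseError(path, len(text), f"expected {n} atom lines")
    names, positions = [], []
    for k in range(n):
        lineno = 3 + k
        line = text[2 + k]
        try:
            names.append(line[10:15].strip())
            positions.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, f"bad coordinate record: {exc}") from None
    box_line = text[2 + n].split()
    try:
        box = float(box_line[0])
    except (ValueError, IndexError):
        raise ParseError(path, 3 + n, "bad box line") from None
    return names, np.asarray(positions, dtype=float).reshape(-1, 3), box


# ---------------------------------------------------------------------------
# .chgtop topology sidecar
# ---------------------------------------------------------------------------

def read_gro_frames(path):
    """All frames of a (possibly multi-frame) GRO file.

    Yields (resnames, atomnames, positions, box_edge) per frame.
    """
    text = Path(path).read_text().splitlines()
    pos = 0
    frames = []
    while pos < len(text):
        if not text[pos].strip() and pos == len(text) - 1:
            break
        if pos + 1 >= len(text):
            raise ParseError(path, pos + 1, "truncated frame header")
        try:
            n = int(text[pos + 1].strip())
        except ValueError:
            raise ParseError(path, pos + 2, f"bad atom count {text[pos + 1]!r}") from None
        if pos + 2 + n >= len(text):
            raise ParseError(path, len(text), f"expected {n} atom lines plus box line")
        resnames, names, coords = [], [], []
        for k in range(n):
            line = text[pos + 2 + k]
            try:
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
                coords.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
            except (ValueError, IndexError) as exc:
                raise ParseError(path, pos + 3 + k, f"bad coordinate record: {exc}") from None
        try:
            box = float(text[pos + 2 + n].split()[0])
        except (ValueError, IndexError):
            raise ParseError(path, pos + 3 + n, "bad box line") from None
        frames.append((resnames, names, np.asarray(coords).reshape(-1, 3), box))
        pos += 3 + n
        while pos < len(text) and not text[pos].strip():
            pos += 1
    return frames


def read_water_frames(path, solute: SoluteStructure | None = None):
    """Water configurations (and optional solute coordinates) from GRO.

    Waters are residues named SOL with sites OW, HW1, HW2 in order.  The
    remaining atoms must match the atom count of ``solute`` when one is
    given; its positions are updated per frame.  Returns a list of
    :class:`~chargecorr.fixtures.WaterFrame`.
    """
    from .fixtures import WaterFrame  # local import to avoid a cycle

    out = []
    for fno, (resnames, names, coords, box) in enumerate(read_gro_frames(path), start=1):
        is_sol = np.array([r == "SOL" for r in resnames])
        wat = coords[is_sol]
        if len(wat) % 3 != 0:
            raise ValueError(f"{path}: frame {fno}: SOL atom count not a multiple of 3")
        wat = wat.reshape(-1, 3, 3)
        frame_solute = None
        other = coords[~is_sol]
        if solute is not None:
            if len(other) != len(solute.atoms):
                raise ValueError(
                    f"{path}: frame {fno}: {len(other)} non-water atoms but the "
                    f"topology describes {len(solute.atoms)}"
                )
            frame_solute = solute.with_positions(other)
        out.append(WaterFrame(wat[:, 0], wat[:, 1], wat[:, 2], box, solute=frame_solute))
    return out


def load_water_models() -> dict:
    """Bundled per-water-model constants (gamma_s, eps, dipole)."""
    with resources.as_file(_data_path("water_models.yaml")) as p:
        return yaml.safe_load(Path(p).read_text())


def write_chgtop(s: SoluteStructure, path) -> None:
    """Charge/topology sidecar: per-atom electrostatic metadata plus
    bonds and exclusion pairs, 1-based indices."""
    lines = ["# chgtop 1", "[atoms]",
             "# index name element group charge radius polar_h"]
    for i, a in enumerate(s.atoms):
        lines.append(f"{i + 1} {a.name} {a.element} {a.group} "
                     f"{a.charge:.6f} {a.radius:.6f} {int(a.is_polar_hydrogen)}")
    lines.append("[bonds]")
    for i, j in s.bonds:
        lines.append(f"{i + 1} {j + 1}")
    lines.append("[exclusions]")
    for pair in sorted(tuple(sorted(p)) for p in s.exclusions):
        lines.append(f"{pair[0] + 1} {pair[1] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_chgtop(path):
    """Parse a .chgtop sidecar into per-atom records, bonds, exclusions."""
    section = None
    atoms, bonds, exclusions = [], [], set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").strip()
            if section not in ("atoms", "bonds", "exclusions"):
                raise ParseError(path, lineno, f"unknown section {section!r}")
            continue
        fields = line.split()
        try:
            if section == "atoms":
                if len(fields) != 7:
                    raise ValueError("expected 7 fields")
                idx = int(fields[0]) - 1
                if idx != len(atoms):
                    raise ValueError(f"atom index {fields[0]} out of order")
                atoms.append(dict(name=fields[1], element=fields[2], group=fields[3],
                                  charge=float(fields[4]), radius=float(fields[5]),
                                  is_polar_hydrogen=bool(int(fields[6]))))
            elif section == "bonds":
                bonds.append((int(fields[0]) - 1, int(fields[1]) - 1))
            elif section == "exclusions":
                exclusions.add(frozenset((int(fields[0]) - 1, int(fields[1]) - 1)))
            else:
                raise ValueError("record outside any section")
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return atoms, bonds, exclusions


def write_structure(s: SoluteStructure, coord_path, topology_path) -> None:
    coord_path = Path(coord_path)
    if coord_path.suffix.lower() == ".pdb":
        write_pdb(s, coord_path)
    elif coord_path.suffix.lower() == ".gro":
        write_gro(s, coord_path)
    else:
        raise ValueError(f"unsupported coordinate format {coord_path.suffix!r}")
    write_chgtop(s, topology_path)


def read_structure(coord_path, topology_path) -> SoluteStructure:
    coord_path = Path(coord_path)
    if coord_path.suffix.lower() == ".pdb":
        names, positions, _elements = read_pdb(coord_path)
    elif coord_path.suffix.lower() == ".gro":
        names, positions, _box = read_gro(coord_path)
    else:
        raise ValueError(f"unsupported coordinate format {coord_path.suffix!r}")
    atom_meta, bonds, exclusions = read_chgtop(topology_path)
    if len(atom_meta) != len(positions):
        raise ValueError(
            f"atom-count mismatch: {len(positions)} coordinates in {coord_path}, "
            f"{len(atom_meta)} atoms in {topology_path}"
        )
    atoms = [
        SoluteAtom(name=m["name"], element=m["element"], position=positions[i],
                   charge=m["charge"], radius=m["radius"],
                   is_polar_hydrogen=m["is_polar_hydrogen"], group=m["group"])
        for i, m in enumerate(atom_meta)
    ]
    return SoluteStructure(atoms, bonds, exclusions, label=coord_path.stem)


# ---------------------------------------------------------------------------
# correction-ledger CSV
# ---------------------------------------------------------------------------

def write_ledger_table(ledgers: Iterable[CorrectionLedger], path) -> None:
    rows = []
    for led in ledgers:
        scheme, _, box = led.scheme_tag.partition(",")
        rows.append([led.guest, led.environment, scheme, box, led.n_water,
                     led.box_edge_L, led.raw, led.dG_pol, led.dG_sum,
                     led.dG_hs, led.dG_excl, led.corrected])
    pd.DataFrame(rows, columns=LEDGER_HEADER).to_csv(path, index=False)


def _ledgers_from_frame(df: pd.DataFrame) -> tuple[list[CorrectionLedger], list[str]]:
    missing = [c for c in LEDGER_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"ledger table missing columns: {missing}")
    ledgers, flagged = [], []
    for _, row in df.iterrows():
        led = CorrectionLedger(
            raw=float(row["raw"]), dG_pol=float(row["dG_pol"]),
            dG_sum=float(row["dG_sum"]), dG_hs=float(row["dG_hs"]),
            dG_excl=float(row["dG_excl"]), corrected=float(row["corrected"]),
            guest=str(row["guest"]), environment=str(row["environment"]),
            scheme_tag=f"{row['scheme']},{row['box']}",
            n_water=int(row["Nw"]), box_edge_L=float(row["L"]),
        )
        ledgers.append(led)
        flagged.extend(led.validate())
    return ledgers, flagged


def read_ledger_table(path) -> tuple[list[CorrectionLedger], list[str]]:
    """Read ledgers from CSV; returns (ledgers, flagged-row messages)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return [], []
    return _ledgers_from_frame(df)


# ---------------------------------------------------------------------------
# bundled benchmark tables (reference charging free energies)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("chargecorr").joinpath("data", name)


def load_benchmark_ledgers() -> tuple[list[CorrectionLedger], list[str]]:
    """Benchmark per-(guest, environment, scheme, box) charging ledgers."""
    with resources.as_file(_data_path("charging_ledgers.csv")) as p:
        return read_ledger_table(p)


def load_benchmark_decomposition() -> pd.DataFrame:
    """Benchmark solvent/host decomposition of the charging free energies."""
    with resources.as_file(_data_path("decomposition.csv")) as p:
        return pd.read_csv(p)


def load_benchmark_binding() -> pd.DataFrame:
    """Benchmark raw charging contributions to binding free energies for
    selected (water-box, host-box) pairings."""
    with resources.as_file(_data_path("binding_combinations.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_run_config(path) -> dict:
    """YAML or JSON mapping of run parameters."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
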