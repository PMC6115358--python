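"""Structure file I/O: XYZ, extended XYZ (with per-site metadata and a
topology sidecar), and LAMMPS data / dump files for interoperability.

All coordinates are written in nm (stated in the comment lines). The
extended-XYZ + ``.topo.json`` pair round-trips a full
:class:`~sorpflex.model.SystemState`: coordinates to print precision
(1e-9 nm), topology and metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import (ROLE_HOST, SimulationBox, SystemState, Topology,
                    empty_state)


class ParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")


# ----------------------------------------------------------------------
# XYZ / extended XYZ
# ----------------------------------------------------------------------

_EXT_COLUMNS = ("species:S:1:pos:R:3:vel:R:3:charge:R:1:sigma:R:1:"
                "epsilon:R:1:mass:R:1:molecule_id:I:1:role:I:1:"
                "donor_h:I:1:acceptor:I:1:donor_o_of:I:1")


def write_xyz(state: SystemState, path):
    """Plain XYZ (labels + coordinates only), units nm."""
    lines = [str(state.n_sites), "units=nm"]
    for s, p in zip(state.species, state.positions):
        lines.append(f"{s} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_extxyz(state: SystemState, path, append: bool = False,
                 write_topology: bool = True):
    """Extended XYZ with per-site metadata; topology goes to a
    ``<path>.topo.json`` sidecar (skipped when appending frames)."""
    L = state.box.lengths
    pbc = " ".join("T" if p else "F" for p in state.box.periodic)
    header = (f'Lattice="{L[0]:.9f} 0.0 0.0 0.0 {L[1]:.9f} 0.0 0.0 0.0 '
              f'{L[2]:.9f}" Properties={_EXT_COLUMNS} pbc="{pbc}" '
              f'frozen_host={"T" if state.frozen_host else "F"} units=nm')
    lines = [str(state.n_sites), header]
    for i in range(state.n_sites):
        p = state.positions[i]
        v = state.velocities[i]
        lines.append(
            f"{state.species[i]} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f} "
            f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f} "
            f"{state.charge[i]:.9f} {state.sigma[i]:.9f} "
            f"{state.epsilon[i]:.9f} {state.mass[i]:.9f} "
            f"{state.molecule_id[i]} {state.role[i]} "
            f"{int(state.donor_h[i])} {int(state.acceptor[i])} "
            f"{state.donor_o_of[i]}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")
    if write_topology and not append:
        _write_topology(state.topology, _topo_path(path))


def _topo_path(path):
    return str(path) + ".topo.json"


def _write_topology(t: Topology, path):
    doc = {
        "bonds": [[int(i), int(j), k, r0] for (i, j), k, r0 in
                  zip(t.bonds, t.bond_k, t.bond_r0)],
        "angles": [[int(i), int(j), int(kk), k, th] for (i, j, kk), k, th in
                   zip(t.angles, t.angle_k, t.angle_theta0)],
        "dihedrals": [[int(i), int(j), int(k), int(l),
                       [[c, int(n), d] for (c, n, d) in coeffs]]
                      for (i, j, k, l, coeffs) in t.dihedrals],
        "rigid_groups": [[int(i) for i in g] for g in t.rigid_groups],
    }
    Path(path).write_text(json.dumps(doc))


def _read_topology(path) -> Topology:
    doc = json.loads(Path(path).read_text())
    bonds = [[b[0], b[1]] for b in doc["bonds"]]
    angles = [[a[0], a[1], a[2]] for a in doc["angles"]]
    return Topology(
        bonds=np.array(bonds) if bonds else None,
        bond_k=[b[2] for b in doc["bonds"]] or None,
        bond_r0=[b[3] for b in doc["bonds"]] or None,
        angles=np.array(angles) if angles else None,
        angle_k=[a[3] for a in doc["angles"]] or None,
        angle_theta0=[a[4] for a in doc["angles"]] or None,
        dihedrals=[(d[0], d[1], d[2], d[3], [tuple(c) for c in d[4]])
                   for d in doc["dihedrals"]],
        rigid_groups=doc["rigid_groups"])


def read_extxyz(path, frame: int = None):
    """Read extended XYZ; returns one SystemState (``frame`` index, default
    last) or, with ``frame='all'``, a list of states. The topology sidecar
    is attached when present."""
    text = Path(path).read_text().splitlines()
    states = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError:
            raise ParseError(path, i + 1, "expected atom count")
        if i + 1 + n >= len(text) + 1:
            raise ParseError(path, i + 1, "truncated frame")
        header = text[i + 1]
        states.append(_parse_ext_frame(header, text[i + 2:i + 2 + n],
                                       path, i + 2))
        i += 2 + n
    if not states:
        raise ParseError(path, 1, "no frames found")
    topo = Path(_topo_path(path))
    if topo.exists():
        t = _read_topology(topo)
        max_idx = max(
            [int(b.max()) for b in (t.bonds, t.angles) if len(b)] +
            [int(g.max()) for g in t.rigid_groups if len(g)] + [-1])
        for s in states:
            if max_idx < s.n_sites:
                s.topology = t.copy()
                s.invalidate_caches()
    if frame == "all":
        return states
    return states[-1 if frame is None else frame]


def _parse_ext_frame(header, lines, path, lineno0):
    import re
    mlat = re.search(r'Lattice="([^"]+)"', header)
    if not mlat:
        raise ParseError(path, lineno0 - 1, "missing Lattice")
    lat = np.array(list(map(float, mlat.group(1).split()))).reshape(3, 3)
    lengths = np.diag(lat)
    mpbc = re.search(r'pbc="([^"]+)"', header)
    periodic = ([t == "T" for t in mpbc.group(1).split()]
                if mpbc else [True] * 3)
    frozen = "frozen_host=T" in header
    n = len(lines)
    if n == 0:
        st = empty_state(SimulationBox(np.maximum(lengths, 1e-9), periodic))
        st.frozen_host = frozen
        return st
    cols = [ln.split() for ln in lines]
    for j, c in enumerate(cols):
        if len(c) != 16:
            raise ParseError(path, lineno0 + j + 1,
                             f"expected 16 columns, got {len(c)}")
    arr = np.array([c[1:] for c in cols], dtype=float)
    st = SystemState(
        SimulationBox(lengths, periodic),
        arr[:, 0:3], np.array([c[0] for c in cols], object),
        arr[:, 6], arr[:, 7], arr[:, 8], arr[:, 9],
        arr[:, 10].astype(np.int64), arr[:, 11].astype(np.int8),
        velocities=arr[:, 3:6],
        donor_h=arr[:, 12] > 0.5, acceptor=arr[:, 13] > 0.5,
        donor_o_of=arr[:, 14].astype(np.int64), frozen_host=frozen)
    return st


# ----------------------------------------------------------------------
# LAMMPS data / dump
# ----------------------------------------------------------------------

def write_lammps_data(state: SystemState, path):
    """LAMMPS data file, atom style ``full`` (units nm as written)."""
    species = sorted(set(state.species))
    type_of = {s: k + 1 for k, s in enumerate(species)}
    t = state.topology
    bond_types = {}
    for k, r0 in zip(t.bond_k, t.bond_r0):
        bond_types.setdefault((k, r0), len(bond_types) + 1)
    angle_types = {}
    for k, th in zip(t.angle_k, t.angle_theta0):
        angle_types.setdefault((k, th), len(angle_types) + 1)
    L = state.box.lengths
    out = ["# sorpflex export (units nm, kJ/mol)", "",
           f"{state.n_sites} atoms", f"{len(t.bonds)} bonds",
           f"{len(t.angles)} angles", "",
           f"{len(species)} atom types", f"{len(bond_types)} bond types",
           f"{len(angle_types)} angle types", "",
           f"0.0 {L[0]:.9f} xlo xhi", f"0.0 {L[1]:.9f} ylo yhi",
           f"0.0 {L[2]:.9f} zlo zhi", "", "Masses", ""]
    mass_of = {}
    for s in species:
        mass_of[s] = float(state.mass[state.species == s][0])
        out.append(f"{type_of[s]} {mass_of[s]:.6f}  # {s}")
    out += ["", "Atoms  # full", ""]
    for i in range(state.n_sites):
        p = state.positions[i]
        out.append(f"{i + 1} {state.molecule_id[i] + 1} "
                   f"{type_of[state.species[i]]} {state.charge[i]:.6f} "
                   f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}")
    if len(t.bonds):
        out += ["", "Bonds", ""]
        for b, ((i, j), k, r0) in enumerate(zip(t.bonds, t.bond_k, t.bond_r0)):
            out.append(f"{b + 1} {bond_types[(k, r0)]} {i + 1} {j + 1}")
    if len(t.angles):
        out += ["", "Angles", ""]
        for a, ((i, j, kk), k, th) in enumerate(
                zip(t.angles, t.angle_k, t.angle_theta0)):
            out.append(f"{a + 1} {angle_types[(k, th)]} {i + 1} {j + 1} {kk + 1}")
    Path(path).write_text("\n".join(out) + "\n")


def read_lammps_data(path) -> SystemState:
    """Read a LAMMPS ``full``-style data file written by this package.

    Species labels are recovered from the ``# label`` comments in the
    Masses section when present; bonded force constants are not stored in
    the data file, so bonds/angles come back with zero parameters."""
    lines = Path(path).read_text().splitlines()
    counts = {}
    L = np.zeros(3)
    section = None
    masses, atoms, bonds, angles = {}, [], [], []
    labels = {}
    for lineno, raw in enumerate(lines, 1):
        bare = raw.split("#")[0].strip()
        if not bare:
            continue
        tok = bare.split()
        if tok[0] in ("Masses", "Atoms", "Bonds", "Angles"):
            section = tok[0]
            continue
        if section is None:
            if len(tok) == 2 and tok[1] in ("atoms", "bonds", "angles"):
                counts[tok[1]] = int(tok[0])
            elif len(tok) == 4 and tok[2] in ("xlo", "ylo", "zlo"):
                lo, hi = float(tok[0]), float(tok[1])
                L["xyz".index(tok[2][0])] = hi - lo
            continue
        try:
            if section == "Masses":
                masses[int(tok[0])] = float(tok[1])
                if "#" in raw:
                    labels[int(tok[0])] = raw.split("#")[1].strip()
            elif section == "Atoms":
                atoms.append((int(tok[0]), int(tok[1]), int(tok[2]),
                              float(tok[3]), *map(float, tok[4:7])))
            elif section == "Bonds":
                bonds.append((int(tok[2]) - 1, int(tok[3]) - 1))
            elif section == "Angles":
                angles.append((int(tok[2]) - 1, int(tok[3]) - 1,
                               int(tok[4]) - 1))
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, f"cannot parse {raw!r}: {exc}")
    atoms.sort()
    n = len(atoms)
    pos = np.array([a[4:7] for a in atoms]) if n else np.zeros((0, 3))
    topo = Topology(bonds=np.array(bonds) if bonds else None,
                    bond_k=np.zeros(len(bonds)) if bonds else None,
                    bond_r0=np.zeros(len(bonds)) if bonds else None,
                    angles=np.array(angles) if angles else None,
                    angle_k=np.zeros(len(angles)) if angles else None,
                    angle_theta0=np.zeros(len(angles)) if angles else None)
    return SystemState(
        SimulationBox(np.maximum(L, 1e-9)), pos,
        np.array([labels.get(a[2], f"T{a[2]}") for a in atoms], object),
        np.array([a[3] for a in atoms]), np.zeros(n), np.zeros(n),
        np.array([masses[a[2]] for a in atoms]) if n else np.ones(0),
        np.array([a[1] - 1 for a in atoms], np.int64),
        np.full(n, ROLE_HOST, np.int8), topo)


def write_lammps_dump(state: SystemState, path, timestep: int = 0,
                      append: bool = False):
    """LAMMPS dump frame: ``id mol type q x y z`` (coordinates nm)."""
    species = sorted(set(state.species))
    type_of = {s: k + 1 for k, s in enumerate(species)}
    L = state.box.lengths
    out = ["ITEM: TIMESTEP", str(timestep),
           "ITEM: NUMBER OF ATOMS", str(state.n_sites),
           "ITEM: BOX BOUNDS pp pp pp",
           f"0.0 {L[0]:.9f}", f"0.0 {L[1]:.9f}", f"0.0 {L[2]:.9f}",
           "ITEM: ATOMS id mol type q x y z"]
    for i in range(state.n_sites):
        p = state.positions[i]
        out.append(f"{i + 1} {state.molecule_id[i] + 1} "
                   f"{type_of[state.species[i]]} {state.charge[i]:.6f} "
                   f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_lammps_dump(path, frame: int = -1) -> SystemState:
    """Read one frame of a dump file (positions, charges, box only)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if lines[i].startswith("ITEM: TIMESTEP"):
            n = int(lines[i + 3])
            L = np.array([float(lines[i + 5 + a].split()[1]) -
                          float(lines[i + 5 + a].split()[0])
                          for a in range(3)])
            rows = [lines[i + 9 + k].split() for k in range(n)]
            rows.sort(key=lambda r: int(r[0]))
            pos = np.array([r[4:7] for r in rows], float)
            st = SystemState(
                SimulationBox(L), pos,
                np.array([f"T{r[2]}" for r in rows], object),
                np.array([float(r[3]) for r in rows]),
                np.zeros(n), np.zeros(n), np.ones(n),
                np.array([int(r[1]) - 1 for r in rows], np.int64),
                np.full(n, ROLE_HOST, np.int8))
            frames.append(st)
            i += 9 + n
        else:
            i += 1
    if not frames:
        raise ParseError(path, 1, "no dump frames found")
    return frames[frame]


# ----------------------------------------------------------------------
FORMATS = {"xyz", "extended-xyz", "lammps-data", "lammps-dump"}


def read_write_structures(path, format: str, state: SystemState = None):
    """Unified front door: write ``state`` when given, else read.

    Supported formats: xyz (write-only round trips labels/coords),
    extended-xyz (full round trip with topology sidecar), lammps-data,
    lammps-dump.
    """
    if format not in FORMATS:
        raise ValueError(f"unrecognized format {format!r}; "
                         f"choose from {sorted(FORMATS)}")
    if state is not None:
        {"xyz": write_xyz, "extended-xyz": write_extxyz,
         "lammps-data": write_lammps_data,
         "lammps-dump": write_lammps_dump}[format](state, path)
        return path
    if format == "xyz":
        raise ValueError("plain xyz carries no box/topology; read via "
                         "extended-xyz")
    return {"extended-xyz": read_extxyz, "lammps-data": read_lammps_data,
            "lammps-dump": read_lammps_dump}[format](path)
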