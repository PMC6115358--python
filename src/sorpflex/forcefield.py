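"""Plain-text forcefield parameter files.

Generic class-I functional forms: per-species mass/charge/LJ in ``[atoms]``,
harmonic ``[bonds]`` and ``[angles]`` keyed by species labels, cosine-series
``[dihedrals]``, and free-form key/value sections (``[rigid]``, ``[meta]``).
Nonbonded cross terms use Lorentz-Berthelot mixing and are computed at
evaluation time, not tabulated here.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass
class AtomType:
    label: str
    mass: float
    charge: float
    sigma: float
    epsilon: float


@dataclass
class ForceField:
    atoms: dict = field(default_factory=dict)           # label -> AtomType
    bonds: dict = field(default_factory=dict)           # frozenset/tuple -> (k, r0)
    angles: dict = field(default_factory=dict)          # (i,j,k) -> (k, theta0_rad)
    dihedrals: dict = field(default_factory=dict)       # (i,j,k,l) -> [(c, n, delta)]
    extra: dict = field(default_factory=dict)           # section -> {key: float}
    source: str = ""
    checksum: str = ""

    def bond_params(self, a: str, b: str):
        try:
            return self.bonds[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no bond parameters for {a}-{b} in {self.source}")

    def angle_params(self, a: str, b: str, c: str):
        for key in ((a, b, c), (c, b, a)):
            if key in self.angles:
                return self.angles[key]
        raise KeyError(f"no angle parameters for {a}-{b}-{c} in {self.source}")


def parse_forcefield(text: str, source: str = "<string>") -> ForceField:
    ff = ForceField(source=source,
                    checksum=hashlib.sha256(text.encode()).hexdigest()[:16])
    section = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        tok = line.split()
        try:
            if section == "atoms":
                label, mass, q, sig, eps = tok[0], *map(float, tok[1:5])
                if mass <= 0 or sig < 0 or eps < 0:
                    raise ValueError("invalid atom parameters")
                ff.atoms[label] = AtomType(label, mass, q, sig, eps)
            elif section == "bonds":
                a, b, k, r0 = tok[0], tok[1], float(tok[2]), float(tok[3])
                ff.bonds[frozenset((a, b))] = (k, r0)
            elif section == "angles":
                a, b, c = tok[0], tok[1], tok[2]
                k, th0 = float(tok[3]), math.radians(float(tok[4]))
                ff.angles[(a, b, c)] = (k, th0)
            elif section == "dihedrals":
                a, b, c, d = tok[0:4]
                vals = list(map(float, tok[4:]))
                terms = [(vals[i], int(vals[i + 1]), math.radians(vals[i + 2]))
                         for i in range(0, len(vals), 3)]
                ff.dihedrals[(a, b, c, d)] = terms
            elif section is not None:
                ff.extra.setdefault(section, {})[tok[0]] = float(tok[1])
            else:
                raise ValueError("data before any [section]")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{source}:{lineno}: cannot parse {raw!r}: {exc}")
    return ff


def load_forcefield(name_or_path) -> ForceField:
    """Load a shipped forcefield by name (``spce``, ``surrogate_host``) or a
    file path."""
    p = Path(str(name_or_path))
    if p.exists():
        return parse_forcefield(p.read_text(), source=str(p))
    res = resources.files("sorpflex.data") / f"{name_or_path}.ff"
    try:
        text = res.read_text()
    except (FileNotFoundError, TypeError):
        raise FileNotFoundError(f"no forcefield named {name_or_path!r}")
    return parse_forcefield(text, source=f"sorpflex.data/{name_or_path}.ff")
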