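"""Molecular data model: periodic box, sites, topology, system state.

The in-memory layout is struct-of-arrays (``numpy`` arrays indexed by site)
for performance; :class:`Site` is a light per-site view used at API
boundaries. Positions are stored *unwrapped*; wrapped views are computed on
demand (see :meth:`SystemState.wrapped_positions`).

Site roles: ``host`` (polymer matrix) or ``water`` (exchangeable adsorbate).
Hydrogen-bond roles are annotated per site: a donor hydrogen knows its
covalently bound donor oxygen; acceptor sites are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_HOST = 0
ROLE_WATER = 1


class InvalidInputError(ValueError):
    """Raised for non-finite or structurally inconsistent inputs."""


class OverlapError(ValueError):
    """Raised when two interacting sites sit closer than the hard-core limit."""


@dataclass
class SimulationBox:
    """Orthorhombic periodic simulation cell.

    Parameters
    ----------
    lengths : (3,) array, nm
    periodic : (3,) bool, which axes are periodic (default all).
    """

    lengths: np.ndarray
    periodic: np.ndarray = None

    def __post_init__(self):
        self.lengths = np.array(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths <= 0):
            raise InvalidInputError("box lengths must be positive and finite")
        if self.periodic is None:
            self.periodic = np.ones(3, dtype=bool)
        else:
            self.periodic = np.array(self.periodic, dtype=bool).reshape(3)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def copy(self) -> "SimulationBox":
        return SimulationBox(self.lengths.copy(), self.periodic.copy())


@dataclass
class Site:
    """Per-site view (API convenience; the hot path uses arrays)."""

    position: np.ndarray
    species_label: str
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    mass: float = 1.0
    molecule_id: int = 0
    role: int = ROLE_HOST
    hb_role: frozenset = frozenset()

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.mass <= 0:
            raise InvalidInputError("mass must be positive")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise InvalidInputError("LJ parameters must be non-negative")


@dataclass
class Topology:
    """Bonded interaction lists and rigid groups.

    Energy conventions (class-I): ``E_bond = k_b (r - r0)^2`` and
    ``E_angle = k_theta (theta - theta0)^2`` (the force constants absorb the
    conventional 1/2). Dihedrals use a cosine series
    ``E = sum_n c_n (1 + cos(n*phi - delta_n))`` given as
    ``(i, j, k, l, [(c_n, n, delta_n), ...])``.
    """

    bonds: np.ndarray = None          # (nb, 2) int
    bond_k: np.ndarray = None         # (nb,) kJ/mol/nm^2
    bond_r0: np.ndarray = None        # (nb,) nm
    angles: np.ndarray = None         # (na, 3) int, vertex is middle index
    angle_k: np.ndarray = None        # (na,) kJ/mol/rad^2
    angle_theta0: np.ndarray = None   # (na,) rad
    dihedrals: list = field(default_factory=list)
    rigid_groups: list = field(default_factory=list)  # list of index arrays

    def __post_init__(self):
        self.bonds = _as_int_array(self.bonds, 2)
        self.angles = _as_int_array(self.angles, 3)
        self.bond_k = _as_float_array(self.bond_k, len(self.bonds))
        self.bond_r0 = _as_float_array(self.bond_r0, len(self.bonds))
        self.angle_k = _as_float_array(self.angle_k, len(self.angles))
        self.angle_theta0 = _as_float_array(self.angle_theta0, len(self.angles))
        self.rigid_groups = [np.asarray(g, dtype=np.int64) for g in self.rigid_groups]
        self.validate()

    def validate(self):
        for name, terms in (("bond", self.bonds), ("angle", self.angles)):
            for t in terms:
                if len(set(int(i) for i in t)) != len(t):
                    raise InvalidInputError(f"{name} term has repeated indices: {t}")
        seen = set()
        for g in self.rigid_groups:
            s = set(int(i) for i in g)
            if seen & s:
                raise InvalidInputError("rigid groups must be disjoint")
            seen |= s

    def copy(self) -> "Topology":
        return Topology(
            bonds=self.bonds.copy(), bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(),
            angles=self.angles.copy(), angle_k=self.angle_k.copy(),
            angle_theta0=self.angle_theta0.copy(),
            dihedrals=[(i, j, k, l, list(c)) for (i, j, k, l, c) in self.dihedrals],
            rigid_groups=[g.copy() for g in self.rigid_groups],
        )


def _as_int_array(a, width):
    if a is None or (hasattr(a, "__len__") and len(a) == 0):
        return np.zeros((0, width), dtype=np.int64)
    return np.asarray(a, dtype=np.int64).reshape(-1, width)


def _as_float_array(a, n):
    if a is None:
        return np.zeros(n, dtype=float)
    out = np.asarray(a, dtype=float).reshape(-1)
    if out.size != n:
        raise InvalidInputError("bonded parameter array length mismatch")
    return out


@dataclass
class EnergyBreakdown:
    lj: float = 0.0
    coulomb: float = 0.0
    bonded: float = 0.0

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.bonded


class SystemState:
    """Full simulation state: box, per-site arrays, topology, velocities.

    Parameters are per-site ``numpy`` arrays; hydrogen-bond roles are encoded
    as ``donor_h`` (bool), ``acceptor`` (bool) and ``donor_o_of`` (for each
    donor hydrogen, the index of its covalent oxygen; -1 elsewhere).
    """

    def __init__(self, box, positions, species, charge, sigma, epsilon, mass,
                 molecule_id, role, topology=None, velocities=None,
                 donor_h=None, acceptor=None, donor_o_of=None,
                 frozen_host=False):
        n = len(positions)
        self.box = box
        self.positions = np.array(positions, dtype=float).reshape(n, 3)
        self.species = np.asarray(species, dtype=object).reshape(n)
        self.charge = np.array(charge, dtype=float).reshape(n)
        self.sigma = np.array(sigma, dtype=float).reshape(n)
        self.epsilon = np.array(epsilon, dtype=float).reshape(n)
        self.mass = np.array(mass, dtype=float).reshape(n)
        self.molecule_id = np.array(molecule_id, dtype=np.int64).reshape(n)
        self.role = np.array(role, dtype=np.int8).reshape(n)
        self.topology = topology if topology is not None else Topology()
        if velocities is None:
            velocities = np.zeros((n, 3))
        self.velocities = np.array(velocities, dtype=float).reshape(n, 3)
        self.donor_h = (np.zeros(n, bool) if donor_h is None
                        else np.array(donor_h, dtype=bool).reshape(n))
        self.acceptor = (np.zeros(n, bool) if acceptor is None
                         else np.array(acceptor, dtype=bool).reshape(n))
        self.donor_o_of = (np.full(n, -1, np.int64) if donor_o_of is None
                           else np.array(donor_o_of, dtype=np.int64).reshape(n))
        self.frozen_host = bool(frozen_host)
        if np.any(self.mass <= 0):
            raise InvalidInputError("site masses must be positive")
        self._excl_cache = None

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_water(self) -> int:
        """Number of water molecules (3 sites each)."""
        n_w_sites = int(np.sum(self.role == ROLE_WATER))
        return n_w_sites // 3

    @property
    def dry_mass(self) -> float:
        """Total mass of host sites, g/mol."""
        return float(np.sum(self.mass[self.role == ROLE_HOST]))

    @property
    def moisture_content(self) -> float:
        """m = mass of water / mass of dry host."""
        wm = float(np.sum(self.mass[self.role == ROLE_WATER]))
        dm = self.dry_mass
        return wm / dm if dm > 0 else np.inf

    def site(self, i: int) -> Site:
        roles = set()
        if self.donor_h[i]:
            roles.add("donor_H")
        if self.acceptor[i]:
            roles.add("acceptor")
        if np.any(self.donor_o_of == i):
            roles.add("donor_O")
        return Site(self.positions[i].copy(), str(self.species[i]),
                    float(self.charge[i]), float(self.sigma[i]),
                    float(self.epsilon[i]), float(self.mass[i]),
                    int(self.molecule_id[i]), int(self.role[i]),
                    frozenset(roles))

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into [0, L) on periodic axes."""
        pos = self.positions.copy()
        for a in range(3):
            if self.box.periodic[a]:
                pos[:, a] %= self.box.lengths[a]
        return pos

    # ------------------------------------------------------------------
    def exclusion_mask(self) -> np.ndarray:
        """(N, N) bool mask; True = pair excluded from nonbonded terms.

        1-2 and 1-3 pairs (from the bond graph) and all intra-rigid-group
        pairs are excluded. Cached until the state is structurally modified.
        """
        if self._excl_cache is not None and self._excl_cache.shape[0] == self.n_sites:
            return self._excl_cache
        n = self.n_sites
        mask = np.zeros((n, n), dtype=bool)
        neigh = [[] for _ in range(n)]
        for i, j in self.topology.bonds:
            neigh[i].append(j)
            neigh[j].append(i)
            mask[i, j] = mask[j, i] = True
        # 1-3 via the bond graph
        for i in range(n):
            for j in neigh[i]:
                for k in neigh[j]:
                    if k != i:
                        mask[i, k] = mask[k, i] = True
        for g in self.topology.rigid_groups:
            mask[np.ix_(g, g)] = True
        np.fill_diagonal(mask, True)
        self._excl_cache = mask
        return mask

    def invalidate_caches(self):
        self._excl_cache = None

    def molecule_sites(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_id == mol_id)

    def water_molecule_ids(self) -> np.ndarray:
        return np.unique(self.molecule_id[self.role == ROLE_WATER])

    # ------------------------------------------------------------------
    def add_water(self, positions3, species3, charge3, sigma3, epsilon3,
                  mass3, donor_h3, acceptor3):
        """Append one rigid 3-site water; returns its molecule id."""
        mol_id = int(self.molecule_id.max()) + 1 if self.n_sites else 0
        n0 = self.n_sites
        self.positions = np.vstack([self.positions, positions3])
        self.species = np.concatenate([self.species, np.asarray(species3, object)])
        self.charge = np.concatenate([self.charge, charge3])
        self.sigma = np.concatenate([self.sigma, sigma3])
        self.epsilon = np.concatenate([self.epsilon, epsilon3])
        self.mass = np.concatenate([self.mass, mass3])
        self.molecule_id = np.concatenate([self.molecule_id, [mol_id] * 3])
        self.role = np.concatenate([self.role, np.full(3, ROLE_WATER, np.int8)])
        self.velocities = np.vstack([self.velocities, np.zeros((3, 3))])
        self.donor_h = np.concatenate([self.donor_h, donor_h3])
        self.acceptor = np.concatenate([self.acceptor, acceptor3])
        # site 0 of the triplet is the oxygen: donor O of both hydrogens
        o_of = np.full(3, -1, np.int64)
        for k in range(3):
            if donor_h3[k]:
                o_of[k] = n0
        self.donor_o_of = np.concatenate([self.donor_o_of, o_of])
        self.topology.rigid_groups.append(np.arange(n0, n0 + 3, dtype=np.int64))
        self.invalidate_caches()
        return mol_id

    def remove_molecule(self, mol_id: int):
        """Delete all sites of one (water) molecule, renumbering indices."""
        idx = self.molecule_sites(mol_id)
        if idx.size == 0:
            raise InvalidInputError(f"no molecule with id {mol_id}")
        keep = np.ones(self.n_sites, dtype=bool)
        keep[idx] = False
        old_to_new = np.cumsum(keep) - 1
        for name in ("positions", "velocities"):
            setattr(self, name, getattr(self, name)[keep])
        for name in ("species", "charge", "sigma", "epsilon", "mass",
                     "molecule_id", "role", "donor_h", "acceptor"):
            setattr(self, name, getattr(self, name)[keep])
        o_of = self.donor_o_of
        new_o = np.full(self.n_sites + idx.size, -1, np.int64)
        valid = o_of >= 0
        new_o[valid] = old_to_new[o_of[valid]]
        self.donor_o_of = new_o[keep]
        t = self.topology
        t.rigid_groups = [old_to_new[g] for g in t.rigid_groups
                          if not np.any(~keep[g])]
        if len(t.bonds):
            bond_keep = ~np.any(~keep[t.bonds], axis=1)
            t.bonds = old_to_new[t.bonds[bond_keep]]
            t.bond_k = t.bond_k[bond_keep]
            t.bond_r0 = t.bond_r0[bond_keep]
        if len(t.angles):
            ang_keep = ~np.any(~keep[t.angles], axis=1)
            t.angles = old_to_new[t.angles[ang_keep]]
            t.angle_k = t.angle_k[ang_keep]
            t.angle_theta0 = t.angle_theta0[ang_keep]
        t.dihedrals = [
            (old_to_new[i], old_to_new[j], old_to_new[k], old_to_new[l], c)
            for (i, j, k, l, c) in t.dihedrals
            if keep[i] and keep[j] and keep[k] and keep[l]
        ]
        self.invalidate_caches()

    def copy(self) -> "SystemState":
        st = SystemState(
            self.box.copy(), self.positions.copy(), self.species.copy(),
            self.charge.copy(), self.sigma.copy(), self.epsilon.copy(),
            self.mass.copy(), self.molecule_id.copy(), self.role.copy(),
            self.topology.copy(), self.velocities.copy(),
            self.donor_h.copy(), self.acceptor.copy(), self.donor_o_of.copy(),
            self.frozen_host)
        return st


def empty_state(box=None) -> SystemState:
    """A valid system with zero sites (dry limit of an empty cell)."""
    if box is None:
        box = SimulationBox(np.ones(3))
    z = np.zeros(0)
    return SystemState(box, np.zeros((0, 3)), np.zeros(0, object), z, z, z,
                       np.zeros(0) + 1.0, np.zeros(0, np.int64),
                       np.zeros(0, np.int8))
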