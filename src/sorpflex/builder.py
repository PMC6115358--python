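"""System builders: amorphous bead-spring polymer hosts and validation
fixtures (bulk water, slit pore, harmonic solid, water pairs).

The surrogate host emulates amorphous cellulose at bead-spring resolution:
each repeat unit is three beads — a heavy backbone bead (CB) and a hydroxyl
donor/acceptor pair (OS, HS) with water-like charges — so the host both
donates and accepts hydrogen bonds while staying cheap enough for
desk-scale sorption campaigns. Chains are grown as self-avoiding random
walks and packed into a periodic box sized to the target density
(1.2 g/cm^3 by default, the standard starting density for amorphous
cellulose packing), then relaxed by NsigmaT dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import NonbondedSettings
from .forcefield import ForceField, load_forcefield
from .md import IntegratorSpec, MDEngine, StabilityError, minimize_energy
from .model import (ROLE_HOST, InvalidInputError, SimulationBox, SystemState,
                    Topology, empty_state)
from .units import density_g_cm3, volume_for_density
from .water import make_water, random_quaternion

HARD_CORE_NM = 0.08  # chains are never grown with any pair closer than this


class BuildError(RuntimeError):
    pass


@dataclass
class BuildRecipe:
    n_chains: int = 3
    units_per_chain: int = 10
    target_density: float = 1.2   # g/cm^3
    seed: int = 1
    box_shape: str = "cubic"
    backbone_step: float = 0.5    # nm, CB-CB bond rest length
    forcefield: str = "surrogate_host"

    def __post_init__(self):
        if self.n_chains < 1 or self.units_per_chain < 2:
            raise InvalidInputError("need >= 1 chain of >= 2 units")
        if self.target_density <= 0:
            raise InvalidInputError("target density must be positive")
        if self.box_shape not in ("cubic", "orthorhombic"):
            raise InvalidInputError(f"unknown box shape {self.box_shape!r}")


def grow_chains(recipe: BuildRecipe, max_restarts: int = 200) -> SystemState:
    """Grow self-avoiding bead-spring chains into a periodic box.

    Each repeat unit contributes CB (backbone), OS and HS (hydroxyl
    donor/acceptor). Deterministic for a given seed.
    """
    ff = load_forcefield(recipe.forcefield)
    cb, os_, hs = ff.atoms["CB"], ff.atoms["OS"], ff.atoms["HS"]
    unit_mass = cb.mass + os_.mass + hs.mass
    total_mass = recipe.n_chains * recipe.units_per_chain * unit_mass
    V = volume_for_density(total_mass, recipe.target_density)
    if recipe.box_shape == "cubic":
        lengths = np.full(3, V ** (1.0 / 3.0))
    else:
        # mildly anisotropic orthorhombic cell with the same volume
        ratios = np.array([0.9, 1.0, 1.0 / 0.9])
        lengths = ratios * V ** (1.0 / 3.0)
    box = SimulationBox(lengths)
    rng = np.random.default_rng(recipe.seed)
    r_cb_os = ff.bond_params("CB", "OS")[1]
    r_os_hs = ff.bond_params("OS", "HS")[1]

    for _ in range(max_restarts):
        placed = []          # all site positions so far
        chains = []          # per chain: list of (cb, os, hs) triples
        ok = True
        for _c in range(recipe.n_chains):
            chain = _grow_one_chain(recipe, rng, lengths, placed,
                                    r_cb_os, r_os_hs)
            if chain is None:
                ok = False
                break
            chains.append(chain)
            for triple in chain:
                placed.extend(triple)
        if ok:
            return _assemble_host(chains, box, ff, recipe)
    achieved = density_g_cm3(total_mass, box.volume)
    raise BuildError(
        f"packing failed after {max_restarts} restarts at density "
        f"{achieved:.3f} g/cm^3; lower target_density or units_per_chain")


def _grow_one_chain(recipe, rng, lengths, placed, r_cb_os, r_os_hs):
    def clash(p, pts, thresh):
        if len(pts) == 0:
            return False
        d = p[None, :] - np.asarray(pts)
        d -= lengths * np.round(d / lengths)
        return bool(np.min(np.einsum("ij,ij->i", d, d)) < thresh * thresh)

    chain = []
    start = rng.random(3) * lengths
    prev_cb = None
    for u in range(recipe.units_per_chain):
        for _try in range(60):
            if prev_cb is None:
                cb_pos = start if _try == 0 else rng.random(3) * lengths
            else:
                v = rng.normal(size=3)
                cb_pos = prev_cb + recipe.backbone_step * v / np.linalg.norm(v)
            others = placed + [p for t in chain for p in t]
            if clash(cb_pos, others, 3.0 * HARD_CORE_NM):
                continue
            v = rng.normal(size=3)
            os_pos = cb_pos + r_cb_os * v / np.linalg.norm(v)
            hs_dir = v / np.linalg.norm(v) + 0.4 * rng.normal(size=3)
            hs_pos = os_pos + r_os_hs * hs_dir / np.linalg.norm(hs_dir)
            if clash(os_pos, others, HARD_CORE_NM) or \
                    clash(hs_pos, others, HARD_CORE_NM):
                continue
            chain.append((cb_pos, os_pos, hs_pos))
            prev_cb = cb_pos
            break
        else:
            return None
    return chain


def _assemble_host(chains, box, ff: ForceField, recipe) -> SystemState:
    positions, species, bonds, bond_params, angles, angle_params = \
        [], [], [], [], [], []
    mol_ids = []
    donor_h, acceptor, donor_o_of = [], [], []
    for mol, chain in enumerate(chains):
        base = len(positions)
        for u, (cbp, osp, hsp) in enumerate(chain):
            i_cb = base + 3 * u
            positions += [cbp, osp, hsp]
            species += ["CB", "OS", "HS"]
            mol_ids += [mol] * 3
            donor_h += [False, False, True]
            acceptor += [False, True, False]
            donor_o_of += [-1, -1, i_cb + 1]
            bonds.append((i_cb, i_cb + 1))
            bond_params.append(ff.bond_params("CB", "OS"))
            bonds.append((i_cb + 1, i_cb + 2))
            bond_params.append(ff.bond_params("OS", "HS"))
            angles.append((i_cb, i_cb + 1, i_cb + 2))
            angle_params.append(ff.angle_params("CB", "OS", "HS"))
            if u > 0:
                prev_cb = base + 3 * (u - 1)
                bonds.append((prev_cb, i_cb))
                bond_params.append(ff.bond_params("CB", "CB"))
                angles.append((prev_cb, i_cb, i_cb + 1))
                angle_params.append(ff.angle_params("CB", "CB", "OS"))
                if u > 1:
                    angles.append((base + 3 * (u - 2), prev_cb, i_cb))
                    angle_params.append(ff.angle_params("CB", "CB", "CB"))
    atom = ff.atoms
    n = len(positions)
    topo = Topology(
        bonds=np.array(bonds), bond_k=[p[0] for p in bond_params],
        bond_r0=[p[1] for p in bond_params],
        angles=np.array(angles), angle_k=[p[0] for p in angle_params],
        angle_theta0=[p[1] for p in angle_params])
    return SystemState(
        box, np.array(positions), np.array(species, object),
        np.array([atom[s].charge for s in species]),
        np.array([atom[s].sigma for s in species]),
        np.array([atom[s].epsilon for s in species]),
        np.array([atom[s].mass for s in species]),
        np.array(mol_ids), np.full(n, ROLE_HOST, np.int8), topo,
        donor_h=donor_h, acceptor=acceptor, donor_o_of=donor_o_of)


def relax_host(state: SystemState, duration: float = 100.0, T: float = 300.0,
               sigma_ext: float = 0.0, seed: int = 0,
               settings: NonbondedSettings = None,
               spec_overrides: dict = None) -> SystemState:
    """NsigmaT relaxation of a freshly grown host.

    Parameters: ``duration`` in ps, ``T`` in K, ``sigma_ext`` in Pa (applied
    on all three axes, tension positive). A short Langevin segment at the
    start absorbs bad contacts from the random growth.
    """
    kw = dict(T_target=T, ensemble="NsigmaT",
              sigma_ext=np.full(3, float(sigma_ext)))
    kw.update(spec_overrides or {})
    spec = IntegratorSpec(**kw)
    rng = np.random.default_rng(seed)
    minimize_energy(state, settings)   # absorb build contacts
    startup = IntegratorSpec(dt=spec.dt, T_target=T, ensemble="NVT",
                             thermostat="langevin", langevin_gamma=20.0)
    eng = MDEngine(state, startup, settings=settings, rng=rng)
    eng.initialize_velocities(T)
    eng.run(max(int(round(2.0 / spec.dt)), 200))  # ~2 ps startup
    eng.spec = spec
    n_steps = int(round(duration / spec.dt))
    eng.run(n_steps, sample_every=max(n_steps // 200, 1))
    epots = [rec["E_pot"] for rec in eng.trace]
    if epots and not np.isfinite(epots[-1]):
        raise StabilityError("host relaxation diverged; reduce dt")
    state.relaxation_trace = eng.trace
    return state


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def make_fixture(kind: str, **kw) -> SystemState:
    """Validation fixtures: ``bulk_water``, ``slit_pore``,
    ``harmonic_solid``, ``two_molecule``."""
    builders = {
        "bulk_water": make_bulk_water,
        "slit_pore": make_slit_pore,
        "harmonic_solid": make_harmonic_solid,
        "two_molecule": make_two_molecule,
    }
    if kind not in builders:
        raise InvalidInputError(f"unknown fixture kind {kind!r}")
    return builders[kind](**kw)


def make_bulk_water(n: int = 216, density: float = 0.997,
                    seed: int = 0) -> SystemState:
    """N rigid SPC/E waters on a jittered cubic lattice at the given
    density (g/cm^3), with random orientations."""
    from .water import water_site_params
    m_water = float(water_site_params()[4].sum())
    V = volume_for_density(n * m_water, density)
    L = V ** (1.0 / 3.0)
    state = empty_state(SimulationBox(np.full(3, L)))
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    a = L / per_side
    count = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if count >= n:
                    break
                pos = (np.array([i, j, k]) + 0.5) * a
                coords, params = make_water(pos, random_quaternion(rng))
                state.add_water(coords, *params)
                count += 1
    return state


def make_slit_pore(gap: float = 1.2, lateral: float = 1.2,
                   spacing: float = 0.1, wall_sigma: float = 0.30,
                   wall_epsilon: float = 0.8, wall_mass: float = 40.0) -> SystemState:
    """One frozen LJ wall layer in a box of height ``gap``: the periodic
    image provides the second wall, so the wall-wall center-to-center
    distance is exactly ``gap``."""
    nxy = max(int(round(lateral / spacing)), 1)
    s = lateral / nxy
    xs = (np.arange(nxy) + 0.5) * s
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    n = X.size
    pos = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n)])
    box = SimulationBox([lateral, lateral, gap])
    state = SystemState(
        box, pos, np.array(["WL"] * n, object), np.zeros(n),
        np.full(n, wall_sigma), np.full(n, wall_epsilon),
        np.full(n, wall_mass), np.zeros(n, np.int64),
        np.full(n, ROLE_HOST, np.int8), frozen_host=True)
    return state


def make_harmonic_solid(n_cells: int = 4, a: float = 0.4, k: float = 500.0,
                        mass: float = 40.0, sigma: float = 0.0,
                        epsilon: float = 0.0) -> SystemState:
    """Simple cubic crystal with nearest-neighbor harmonic springs
    (E = k (r - a)^2), fully bonded across periodic boundaries."""
    L = n_cells * a
    idx = lambda i, j, kk: ((i % n_cells) * n_cells + (j % n_cells)) * n_cells + (kk % n_cells)
    pos, bonds = [], []
    for i in range(n_cells):
        for j in range(n_cells):
            for kk in range(n_cells):
                pos.append([i * a, j * a, kk * a])
                bonds += [(idx(i, j, kk), idx(i + 1, j, kk)),
                          (idx(i, j, kk), idx(i, j + 1, kk)),
                          (idx(i, j, kk), idx(i, j, kk + 1))]
    n = len(pos)
    # periodic wrap at n_cells <= 2 would duplicate (or self-)bond pairs
    seen = set()
    bonds = [b for b in bonds
             if b[0] != b[1] and frozenset(b) not in seen
             and not seen.add(frozenset(b))]
    topo = Topology(bonds=np.array(bonds) if bonds else None,
                    bond_k=np.full(len(bonds), k) if bonds else None,
                    bond_r0=np.full(len(bonds), a) if bonds else None)
    return SystemState(
        SimulationBox(np.full(3, L)), np.array(pos, float),
        np.array(["XB"] * n, object), np.zeros(n), np.full(n, sigma),
        np.full(n, epsilon), np.full(n, mass), np.zeros(n, np.int64),
        np.full(n, ROLE_HOST, np.int8), topo)


def make_two_molecule(separation: float = 0.28, box_length: float = 5.0,
                      orientation1=(1.0, 0, 0, 0),
                      orientation2=(1.0, 0, 0, 0)) -> SystemState:
    """Two rigid waters with oxygen-oxygen separation along x; a
    configurable hydrogen-bond-geometry pair."""
    state = empty_state(SimulationBox(np.full(3, box_length)))
    c = box_length / 2.0
    coords, params = make_water(np.array([c, c, c]), orientation1)
    state.add_water(coords, *params)
    coords, params = make_water(np.array([c + separation, c, c]), orientation2)
    state.add_water(coords, *params)
    return state
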