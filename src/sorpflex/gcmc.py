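"""Grand-canonical Monte Carlo for water against an ideal-vapor reservoir.

The reservoir fixes (mu, T). Relative humidity maps onto chemical potential
through the ideal-vapor relation mu - mu0 = k_B T ln RH, anchored at the
bulk saturation pressure of the water model (P0 = 1017 Pa for SPC/E at
300 K), so the insertion/deletion activity is z = P / (k_B T) with
P = RH * P0. Host sites are never touched by GCMC moves.

Acceptance rules (Metropolis, standard grand-canonical weights):

* insert:    min{1, z V / (N+1) * exp(-beta dU)}
* delete:    min{1, N / (z V) * exp(-beta dU)}
* translate / rotate: min{1, exp(-beta dU)}
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .energy import NonbondedSettings
from .model import InvalidInputError, SystemState
from .units import KB, P0_SPCE_PA, pressure_pa_to_internal
from .water import make_water, quaternion_to_matrix, random_quaternion


@dataclass
class ReservoirSpec:
    """Ideal-vapor water reservoir at (T, RH)."""

    T: float = 300.0
    RH: float = 0.5
    P0: float = P0_SPCE_PA      # Pa

    def __post_init__(self):
        if self.T <= 0:
            raise InvalidInputError("T must be positive")
        if not (0.0 <= self.RH <= 1.0):
            raise InvalidInputError("RH must lie in [0, 1]")

    @property
    def mu_offset(self) -> float:
        """mu - mu0 in kJ/mol (the dry limit RH = 0 has no finite mu)."""
        if self.RH == 0.0:
            return -math.inf
        return KB * self.T * math.log(self.RH)

    @property
    def pressure_internal(self) -> float:
        """Vapor pressure P = RH * P0 in internal units (kJ/mol/nm^3)."""
        return pressure_pa_to_internal(self.RH * self.P0)

    @property
    def activity(self) -> float:
        """Ideal-gas activity z = P/(k_B T) in nm^-3."""
        return self.pressure_internal / (KB * self.T)


def rh_to_mu(RH: float, T: float, P0: float = P0_SPCE_PA):
    """(mu - mu0 in kJ/mol, activity z in nm^-3) for an ideal vapor.

    RH = 0 is the dry limit: mu_offset is -inf and the activity is 0 (no
    insertions), which is how the sorption driver treats a dry sweep end.
    """
    if RH < 0 or RH > 1:
        raise InvalidInputError("RH must lie in [0, 1]")
    res = ReservoirSpec(T=T, RH=RH, P0=P0)
    return res.mu_offset, res.activity


@dataclass
class MoveStats:
    attempted: dict = field(default_factory=lambda: {
        "insert": 0, "delete": 0, "translate": 0, "rotate": 0})
    accepted: dict = field(default_factory=lambda: {
        "insert": 0, "delete": 0, "translate": 0, "rotate": 0})

    def record(self, kind: str, ok: bool):
        self.attempted[kind] += 1
        if ok:
            self.accepted[kind] += 1

    def ratio(self, kind: str) -> float:
        a = self.attempted[kind]
        return self.accepted[kind] / a if a else float("nan")

    def merge(self, other: "MoveStats"):
        for k in self.attempted:
            self.attempted[k] += other.attempted[k]
            self.accepted[k] += other.accepted[k]


def acceptance_probability(kind: str, n_water: int, volume: float,
                           activity: float, dU: float, T: float) -> float:
    """Grand-canonical Metropolis acceptance probability (exposed for
    detailed-balance checks)."""
    beta = 1.0 / (KB * T)
    if not np.isfinite(dU):
        boltz = 0.0 if dU > 0 else math.inf
    else:
        x = -beta * dU
        boltz = 0.0 if x <= -700.0 else math.exp(min(x, 700.0))
    if kind == "insert":
        return min(1.0, activity * volume / (n_water + 1) * boltz)
    if kind == "delete":
        if n_water == 0:
            return 0.0
        return min(1.0, n_water / (activity * volume) * boltz)
    if kind in ("translate", "rotate"):
        return min(1.0, boltz)
    raise InvalidInputError(f"unknown move kind {kind!r}")


class GCMCEngine:
    """Water-exchange Monte Carlo bound to one :class:`SystemState`."""

    def __init__(self, state: SystemState, reservoir: ReservoirSpec, rng,
                 settings: NonbondedSettings = None,
                 max_displacement: float = 0.03, max_rotation: float = 0.4):
        self.state = state
        self.reservoir = reservoir
        self.rng = rng
        self.settings = settings or NonbondedSettings()
        self.max_displacement = max_displacement  # nm
        self.max_rotation = max_rotation          # rad

    # -- energies -------------------------------------------------------
    def _molecule_external_energy(self, sel) -> float:
        st = self.state
        return float(_kernels.group_external_energy(
            st.positions, st.box.lengths, st.box.periodic, st.charge,
            st.sigma, st.epsilon, st.molecule_id,
            np.asarray(sel, np.int64), self.settings.cutoff,
            self.settings.dsf_alpha))

    def _trial_energy(self, coords, params) -> float:
        st = self.state
        _, charge, sigma, epsilon, _, _, _ = params
        return float(_kernels.trial_insertion_energy(
            st.positions, st.box.lengths, st.box.periodic, st.charge,
            st.sigma, st.epsilon, np.asarray(coords, float),
            charge, sigma, epsilon,
            self.settings.cutoff, self.settings.dsf_alpha))

    # -- moves ----------------------------------------------------------
    def attempt_move(self, kind: str):
        """One GCMC attempt; returns (accepted, flag)."""
        st = self.state
        res = self.reservoir
        rng = self.rng
        z = res.activity
        V = st.box.volume
        n_w = st.n_water

        if kind == "insert":
            if z == 0.0:
                return False, "dry"
            pos = rng.random(3) * st.box.lengths
            coords, params = make_water(pos, random_quaternion(rng))
            dU = self._trial_energy(coords, params)
            p = acceptance_probability("insert", n_w, V, z, dU, res.T)
            if rng.random() < p:
                st.add_water(coords, *params)
                return True, ""
            return False, ""

        if kind == "delete":
            if n_w == 0:
                return False, "empty"
            if z == 0.0:
                # z -> 0 limit of the delete weight N/(zV) e^{-beta dU} is
                # +inf: deletions are always accepted in the dry limit
                mol = rng.choice(st.water_molecule_ids())
                st.remove_molecule(int(mol))
                return True, ""
            mol = int(rng.choice(st.water_molecule_ids()))
            sel = st.molecule_sites(mol)
            dU = -self._molecule_external_energy(sel)
            p = acceptance_probability("delete", n_w, V, z, dU, res.T)
            if rng.random() < p:
                st.remove_molecule(mol)
                return True, ""
            return False, ""

        if kind in ("translate", "rotate"):
            if n_w == 0:
                return False, "empty"
            mol = int(rng.choice(st.water_molecule_ids()))
            sel = st.molecule_sites(mol)
            e_old = self._molecule_external_energy(sel)
            old = st.positions[sel].copy()
            if kind == "translate":
                st.positions[sel] += (rng.random(3) * 2.0 - 1.0) * self.max_displacement
            else:
                m = st.mass[sel][:, None]
                com = np.sum(m * st.positions[sel], axis=0) / m.sum()
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = (rng.random() * 2.0 - 1.0) * self.max_rotation
                half = ang / 2.0
                quat = np.concatenate([[math.cos(half)], math.sin(half) * axis])
                R = quaternion_to_matrix(quat)
                st.positions[sel] = com + (st.positions[sel] - com) @ R.T
            dU = self._molecule_external_energy(sel) - e_old
            p = acceptance_probability(kind, n_w, st.box.volume, z, dU, res.T)
            if rng.random() < p:
                return True, ""
            st.positions[sel] = old
            return False, ""

        raise InvalidInputError(f"unknown move kind {kind!r}")


DEFAULT_MOVE_MIX = {"insert": 0.25, "delete": 0.25,
                    "translate": 0.3, "rotate": 0.2}


def attempt_move(state: SystemState, kind: str, reservoir: ReservoirSpec,
                 rng, settings: NonbondedSettings = None):
    """One-shot functional wrapper around :class:`GCMCEngine`."""
    eng = GCMCEngine(state, reservoir, rng, settings)
    return state, eng.attempt_move(kind)[0]


def run_gcmc_block(state: SystemState, reservoir: ReservoirSpec,
                   n_moves: int, move_mix: dict = None, rng=None,
                   settings: NonbondedSettings = None,
                   engine: GCMCEngine = None):
    """Run ``n_moves`` GCMC attempts; returns (state, MoveStats)."""
    mix = dict(DEFAULT_MOVE_MIX if move_mix is None else move_mix)
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidInputError("move mix probabilities must sum to 1")
    if engine is None:
        engine = GCMCEngine(state, reservoir,
                            rng if rng is not None else np.random.default_rng(0),
                            settings)
    stats = MoveStats()
    cum = np.cumsum(probs)
    for _ in range(n_moves):
        kind = kinds[int(np.searchsorted(cum, engine.rng.random()))]
        ok, _flag = engine.attempt_move(kind)
        stats.record(kind, ok)
    return state, stats
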