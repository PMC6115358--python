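"""Energy and force evaluation.

Nonbonded: 12-6 Lennard-Jones (Lorentz-Berthelot mixing, truncated at the
cutoff, unshifted) plus damped-shifted-force Coulomb, both evaluated at the
minimum-image separation. Bonded: harmonic bonds and angles and a cosine
dihedral series (class-I forms; force constants follow the
``E = k (delta)^2`` convention of the shipped parameter files).

The default electrostatics is DSF with ``alpha = 2.0 nm^-1`` and a 0.9 nm
cutoff; both are plain parameters and recorded in run manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import EnergyBreakdown, InvalidInputError, OverlapError, SimulationBox, SystemState
from .units import COULOMB_K

DEFAULT_CUTOFF = 0.9      # nm
DEFAULT_DSF_ALPHA = 0.0   # nm^-1; 0 = undamped shifted-force limit


@dataclass
class NonbondedSettings:
    cutoff: float = DEFAULT_CUTOFF
    dsf_alpha: float = DEFAULT_DSF_ALPHA

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InvalidInputError("cutoff must be positive")


def minimum_image(r1, r2, box: SimulationBox) -> np.ndarray:
    """Minimum-image displacement from ``r1`` to ``r2`` (i.e. ``r2 - r1``),
    with the exact half-box tie broken toward +L/2."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if not (np.all(np.isfinite(r1)) and np.all(np.isfinite(r2))):
        raise InvalidInputError("non-finite coordinates")
    d = r2 - r1
    L = box.lengths
    for a in range(3):
        if box.periodic[a]:
            d[..., a] -= L[a] * np.floor(d[..., a] / L[a] + 0.5)
            # floor(x+0.5) maps the exact half-box tie to -L/2; flip it
            if np.isscalar(d[..., a]) or d.ndim == 1:
                if d[a] == -0.5 * L[a]:
                    d[a] = 0.5 * L[a]
            else:
                d[..., a][d[..., a] == -0.5 * L[a]] = 0.5 * L[a]
    return d


def minimum_image_table(ra, rb, box: SimulationBox) -> np.ndarray:
    """(len(ra), len(rb), 3) minimum-image displacement table (vectorized)."""
    d = np.asarray(ra)[:, None, :] - np.asarray(rb)[None, :, :]
    L = box.lengths
    for a in range(3):
        if box.periodic[a]:
            d[..., a] -= L[a] * np.round(d[..., a] / L[a])
    return d


def pair_energy(si, sj, box: SimulationBox, cutoff: float = DEFAULT_CUTOFF,
                dsf_alpha: float = DEFAULT_DSF_ALPHA) -> float:
    """Nonbonded energy (kJ/mol) of two sites at minimum image.

    Lorentz-Berthelot mixing; zero beyond the cutoff. Raises
    :class:`OverlapError` for interacting sites closer than 1e-6 nm.
    """
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    d = minimum_image(si.position, sj.position, box)
    r = float(np.linalg.norm(d))
    interacting = (si.lj_epsilon * sj.lj_epsilon > 0) or (si.charge * sj.charge != 0)
    if r < 1.0e-6 and interacting:
        raise OverlapError(f"sites overlap at r = {r:g} nm")
    if r >= cutoff:
        return 0.0
    e = 0.0
    eps_ij = math.sqrt(si.lj_epsilon * sj.lj_epsilon)
    if eps_ij > 0:
        sig_ij = 0.5 * (si.lj_sigma + sj.lj_sigma)
        sr6 = (sig_ij / r) ** 6
        e += 4.0 * eps_ij * (sr6 * sr6 - sr6)
    qq = si.charge * sj.charge
    if qq != 0.0:
        e_rc, f_rc = _kernels._dsf_shift_terms(dsf_alpha, cutoff)
        if dsf_alpha > 0:
            e += COULOMB_K * qq * (math.erfc(dsf_alpha * r) / r - e_rc
                                   + f_rc * (r - cutoff))
        else:
            e += COULOMB_K * qq * (1.0 / r - e_rc + f_rc * (r - cutoff))
    return float(e)


def nonbonded_energy(state: SystemState, settings: NonbondedSettings = None,
                     want_forces: bool = False):
    """(e_lj, e_coul, forces, virial) for the whole system."""
    if settings is None:
        settings = NonbondedSettings()
    excl = state.exclusion_mask()
    e_lj, e_c, forces, virial = _kernels.nonbonded_energy_forces(
        state.positions, state.box.lengths, state.box.periodic,
        state.charge, state.sigma, state.epsilon, excl,
        settings.cutoff, settings.dsf_alpha, want_forces)
    return e_lj, e_c, forces, virial


def bonded_energy_forces(state: SystemState, want_forces: bool = False):
    """(energy, forces, virial) of bonds + angles + dihedrals.

    Relative vectors within each term use the minimum image, so wrapped and
    unwrapped coordinate sets give identical results as long as no bonded
    term spans more than half a box length.
    """
    t = state.topology
    pos = state.positions
    box = state.box
    n = state.n_sites
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    e = 0.0

    if len(t.bonds):
        i, j = t.bonds[:, 0], t.bonds[:, 1]
        d = _min_image_rows(pos[i] - pos[j], box)
        r = np.linalg.norm(d, axis=1)
        dr = r - t.bond_r0
        e += float(np.sum(t.bond_k * dr * dr))
        if want_forces:
            # E = k dr^2 -> |F| = 2 k dr, directed along the bond
            fmag = -2.0 * t.bond_k * dr / np.where(r > 0, r, 1.0)
            fvec = fmag[:, None] * d
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)
            virial += np.sum(fvec * d, axis=0)

    if len(t.angles):
        ia, ja, ka = t.angles[:, 0], t.angles[:, 1], t.angles[:, 2]
        r_ij = _min_image_rows(pos[ia] - pos[ja], box)
        r_kj = _min_image_rows(pos[ka] - pos[ja], box)
        nij = np.linalg.norm(r_ij, axis=1)
        nkj = np.linalg.norm(r_kj, axis=1)
        cosv = np.sum(r_ij * r_kj, axis=1) / (nij * nkj)
        cosv = np.clip(cosv, -1.0, 1.0)
        theta = np.arccos(cosv)
        dth = theta - t.angle_theta0
        e += float(np.sum(t.angle_k * dth * dth))
        if want_forces:
            sinv = np.sqrt(np.maximum(1.0 - cosv * cosv, 1.0e-12))
            dEdth = 2.0 * t.angle_k * dth
            # dtheta/dr_i = (cos * u_ij - u_kj) / (|r_ij| sin)
            u_ij = r_ij / nij[:, None]
            u_kj = r_kj / nkj[:, None]
            fi = -dEdth[:, None] * (cosv[:, None] * u_ij - u_kj) / (nij * sinv)[:, None]
            fk = -dEdth[:, None] * (cosv[:, None] * u_kj - u_ij) / (nkj * sinv)[:, None]
            fj = -(fi + fk)
            np.add.at(forces, ia, fi)
            np.add.at(forces, ja, fj)
            np.add.at(forces, ka, fk)
            virial += np.sum(fi * r_ij + fk * r_kj, axis=0)

    for (i, j, k, l, coeffs) in t.dihedrals:
        b1 = _min_image_rows((pos[j] - pos[i])[None, :], box)[0]
        b2 = _min_image_rows((pos[k] - pos[j])[None, :], box)[0]
        b3 = _min_image_rows((pos[l] - pos[k])[None, :], box)[0]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        phi = np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
        dEdphi = 0.0
        for (c, mult, delta) in coeffs:
            e += c * (1.0 + np.cos(mult * phi - delta))
            dEdphi += -c * mult * np.sin(mult * phi - delta)
        if want_forces:
            sq1 = np.dot(n1, n1)
            sq2 = np.dot(n2, n2)
            if sq1 < 1e-12 or sq2 < 1e-12:
                continue
            dphi_di = -(nb2 / sq1) * n1
            dphi_dl = (nb2 / sq2) * n2
            c12 = np.dot(b1, b2) / (nb2 * nb2)
            c32 = np.dot(b3, b2) / (nb2 * nb2)
            dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
            dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
            fi = -dEdphi * dphi_di
            fj = -dEdphi * dphi_dj
            fk = -dEdphi * dphi_dk
            fl = -dEdphi * dphi_dl
            for idx, f in ((i, fi), (j, fj), (k, fk), (l, fl)):
                forces[idx] += f
            # virial from positions relative to atom j (term-local frame)
            virial += fi * (-b1) + fk * b2 + fl * (b2 + b3)
    return e, forces, virial


def _min_image_rows(d, box: SimulationBox) -> np.ndarray:
    d = np.array(d, dtype=float)
    L = box.lengths
    for a in range(3):
        if box.periodic[a]:
            d[:, a] -= L[a] * np.round(d[:, a] / L[a])
    return d


def total_energy(state: SystemState, cutoff: float = DEFAULT_CUTOFF,
                 dsf_alpha: float = DEFAULT_DSF_ALPHA) -> EnergyBreakdown:
    """Total potential energy with 1-2/1-3 exclusions applied."""
    if state.n_sites == 0:
        return EnergyBreakdown()
    settings = NonbondedSettings(cutoff=cutoff, dsf_alpha=dsf_alpha)
    e_lj, e_c, _, _ = nonbonded_energy(state, settings)
    e_b, _, _ = bonded_energy_forces(state)
    return EnergyBreakdown(lj=float(e_lj), coulomb=float(e_c), bonded=float(e_b))


def total_forces(state: SystemState, settings: NonbondedSettings = None):
    """(forces (N,3), potential energy, virial (3,)) for MD."""
    if settings is None:
        settings = NonbondedSettings()
    e_lj, e_c, f_nb, w_nb = nonbonded_energy(state, settings, want_forces=True)
    e_b, f_b, w_b = bonded_energy_forces(state, want_forces=True)
    return f_nb + f_b, float(e_lj + e_c + e_b), w_nb + w_b
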