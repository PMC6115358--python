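"""Numba kernels for the nonbonded inner loops.

Nonbonded model: truncated (unshifted) 12-6 Lennard-Jones with
Lorentz-Berthelot mixing, plus damped-shifted-force (DSF) real-space
Coulomb. ``alpha = 0`` reduces DSF to the undamped shifted-force scheme.
Energies in kJ/mol, distances in nm.
"""

import math

import numpy as np
from numba import njit

from .units import COULOMB_K

#: energy assigned to a hard overlap (keeps MC acceptance exactly zero)
OVERLAP_ENERGY = 1.0e30
_R2_MIN = 1.0e-12  # nm^2


@njit(cache=True, fastmath=True)
def _dsf_shift_terms(alpha, rc):
    """(energy shift at rc, force shift) for the DSF Coulomb scheme."""
    if alpha > 0.0:
        erfc_rc = math.erfc(alpha * rc)
        e_rc = erfc_rc / rc
        f_rc = erfc_rc / (rc * rc) + 2.0 * alpha / math.sqrt(math.pi) * \
            math.exp(-alpha * alpha * rc * rc) / rc
    else:
        e_rc = 1.0 / rc
        f_rc = 1.0 / (rc * rc)
    return e_rc, f_rc


@njit(cache=True, fastmath=True)
def nonbonded_energy_forces(pos, lengths, periodic, q, sig, eps, excl,
                            rc, alpha, want_forces):
    """Full pairwise nonbonded evaluation.

    Returns (e_lj, e_coul, forces (N,3), virial (3,)) where
    ``virial[a] = sum_pairs f_ij,a * dx_ij,a`` (f on i, dx = r_i - r_j).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    e_lj = 0.0
    e_c = 0.0
    rc2 = rc * rc
    e_rc, f_rc = _dsf_shift_terms(alpha, rc)
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if periodic[0]:
                dx -= lengths[0] * round(dx / lengths[0])
            if periodic[1]:
                dy -= lengths[1] * round(dy / lengths[1])
            if periodic[2]:
                dz -= lengths[2] * round(dz / lengths[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < _R2_MIN:
                e_lj += OVERLAP_ENERGY
                continue
            qq = q[i] * q[j]
            # Lorentz-Berthelot mixing
            s_ij = 0.5 * (sig[i] + sig[j])
            e_ij = math.sqrt(eps[i] * eps[j])
            fr = 0.0  # (dE/dr)/r accumulated with sign so F_i = -fr * d
            if e_ij > 0.0:
                sr2 = s_ij * s_ij / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e_lj += 4.0 * e_ij * (sr12 - sr6)
                fr += 24.0 * e_ij * (2.0 * sr12 - sr6) / r2
            if qq != 0.0:
                r = math.sqrt(r2)
                if alpha > 0.0:
                    erfc_r = math.erfc(alpha * r)
                    e_c += COULOMB_K * qq * (erfc_r / r - e_rc + f_rc * (r - rc))
                    fmag = COULOMB_K * qq * (
                        erfc_r / r2
                        + 2.0 * alpha / math.sqrt(math.pi)
                        * math.exp(-alpha * alpha * r2) / r
                        - f_rc)
                else:
                    e_c += COULOMB_K * qq * (1.0 / r - e_rc + f_rc * (r - rc))
                    fmag = COULOMB_K * qq * (1.0 / r2 - f_rc)
                fr += fmag / r
            if want_forces and fr != 0.0:
                fx = fr * dx
                fy = fr * dy
                fz = fr * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                virial[0] += fx * dx
                virial[1] += fy * dy
                virial[2] += fz * dz
    return e_lj, e_c, forces, virial


@njit(cache=True, fastmath=True)
def group_external_energy(pos, lengths, periodic, q, sig, eps, molecule_id,
                          sel, rc, alpha):
    """Nonbonded energy between sites ``sel`` and all sites of *other*
    molecules (used for GCMC single-molecule moves)."""
    n = pos.shape[0]
    rc2 = rc * rc
    e_rc, f_rc = _dsf_shift_terms(alpha, rc)
    e = 0.0
    for a in range(sel.shape[0]):
        i = sel[a]
        mi = molecule_id[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(n):
            if molecule_id[j] == mi:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if periodic[0]:
                dx -= lengths[0] * round(dx / lengths[0])
            if periodic[1]:
                dy -= lengths[1] * round(dy / lengths[1])
            if periodic[2]:
                dz -= lengths[2] * round(dz / lengths[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < _R2_MIN:
                e += OVERLAP_ENERGY
                continue
            e_ij = math.sqrt(eps[i] * eps[j])
            if e_ij > 0.0:
                s_ij = 0.5 * (sig[i] + sig[j])
                sr2 = s_ij * s_ij / r2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * e_ij * (sr6 * sr6 - sr6)
            qq = q[i] * q[j]
            if qq != 0.0:
                r = math.sqrt(r2)
                if alpha > 0.0:
                    e += COULOMB_K * qq * (math.erfc(alpha * r) / r - e_rc
                                           + f_rc * (r - rc))
                else:
                    e += COULOMB_K * qq * (1.0 / r - e_rc + f_rc * (r - rc))
    return e


@njit(cache=True, fastmath=True)
def trial_insertion_energy(pos, lengths, periodic, q, sig, eps,
                           new_pos, new_q, new_sig, new_eps, rc, alpha):
    """Energy of a trial molecule (arrays of its sites) with every existing
    site. Intra-trial terms are excluded (rigid molecule)."""
    n = pos.shape[0]
    rc2 = rc * rc
    e_rc, f_rc = _dsf_shift_terms(alpha, rc)
    e = 0.0
    for a in range(new_pos.shape[0]):
        xi = new_pos[a, 0]
        yi = new_pos[a, 1]
        zi = new_pos[a, 2]
        for j in range(n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if periodic[0]:
                dx -= lengths[0] * round(dx / lengths[0])
            if periodic[1]:
                dy -= lengths[1] * round(dy / lengths[1])
            if periodic[2]:
                dz -= lengths[2] * round(dz / lengths[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            if r2 < _R2_MIN:
                e += OVERLAP_ENERGY
                continue
            e_ij = math.sqrt(new_eps[a] * eps[j])
            if e_ij > 0.0:
                s_ij = 0.5 * (new_sig[a] + sig[j])
                sr2 = s_ij * s_ij / r2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * e_ij * (sr6 * sr6 - sr6)
            qq = new_q[a] * q[j]
            if qq != 0.0:
                r = math.sqrt(r2)
                if alpha > 0.0:
                    e += COULOMB_K * qq * (math.erfc(alpha * r) / r - e_rc
                                           + f_rc * (r - rc))
                else:
                    e += COULOMB_K * qq * (1.0 / r - e_rc + f_rc * (r - rc))
    return e
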