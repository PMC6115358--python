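"""Hydrogen-bond detection, classification, energetics and related
structure analysis (RDFs, density maps, scaling fits, capillary shift).

A hydrogen bond is detected geometrically: a donor O-H and an acceptor
(O-type) site on a *different* molecule, with

* a distance cutoff ``d_max`` (default 0.35 nm) applied either to the
  donor-O...acceptor distance (``O_to_O``, the common literature
  convention and the default) or to the H...acceptor distance
  (``O_to_H``), and
* an angular cutoff ``angle_max`` (default 30 deg), measured by default
  at the donor oxygen (angle between the covalent O-H bond and the
  O...acceptor vector); the deviation-from-linearity-at-H variant is
  available.

The default pairing (O...O < 0.35 nm, donor angle < 30 deg) reproduces
the standard bulk-water benchmark of ~3.6 hydrogen bonds per molecule for
rigid 3-site water at 300 K; the alternative conventions are kept
first-class because the wording of geometric criteria varies across the
literature.

Bond classes: WW (water-water), CW (host-water, either direction), CC
(host-host). Counts are normalized per water molecule (WW, CW) or per host
repeat unit (CC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import stats

from .energy import minimum_image_table
from .model import ROLE_WATER, InvalidInputError, SystemState
from .units import COULOMB_K, KJ_TO_KCAL


@dataclass
class HBCriterion:
    """Geometric hydrogen-bond criterion.

    ``angle_convention``: where the 30-degree donor-acceptor angle is
    measured. ``donor`` (default) is the common literature convention —
    the angle at the donor oxygen between the covalent O-H bond and the
    O...acceptor vector; ``hydrogen`` measures the deviation from
    linearity of donor-O - H ... acceptor at the hydrogen instead.
    """

    d_max: float = 0.35                  # nm
    angle_max: float = 30.0              # degrees
    distance_convention: str = "O_to_O"  # or "O_to_H"
    angle_convention: str = "donor"      # or "hydrogen"

    def __post_init__(self):
        if self.d_max <= 0:
            raise InvalidInputError("d_max must be positive")
        if not (0.0 < self.angle_max < 90.0):
            raise InvalidInputError("angle_max must be in (0, 90) degrees")
        if self.distance_convention not in ("O_to_H", "O_to_O"):
            raise InvalidInputError(
                f"unknown distance convention {self.distance_convention!r}")
        if self.angle_convention not in ("donor", "hydrogen"):
            raise InvalidInputError(
                f"unknown angle convention {self.angle_convention!r}")


@dataclass
class HBRecord:
    donor_o: int
    donor_h: int
    acceptor: int
    hb_class: str                        # WW | CW | CC
    energy: float = None                 # kcal/mol binding magnitude


@dataclass
class HBSummary:
    hb_ww_per_water: float = math.nan
    hb_cw_per_water: float = math.nan
    hb_cc_per_unit: float = 0.0
    n_ww_raw: int = 0
    n_cw_raw: int = 0
    n_cc_raw: int = 0
    fraction_water_bound_to_host: float = math.nan
    n_water: int = 0
    n_host_units: int = 0

    @property
    def hb_total_per_water(self) -> float:
        return self.hb_ww_per_water + self.hb_cw_per_water


def detect_hbonds(frame: SystemState, crit: HBCriterion = None) -> List[HBRecord]:
    """All hydrogen bonds of a frame under the geometric criterion.

    One record per (donor H, acceptor) pair passing both cutoffs; donor and
    acceptor must belong to different molecules.
    """
    crit = crit or HBCriterion()
    h_idx = np.flatnonzero(frame.donor_h)
    a_idx = np.flatnonzero(frame.acceptor)
    if h_idx.size == 0 or a_idx.size == 0:
        return []
    o_idx = frame.donor_o_of[h_idx]
    pos = frame.positions
    box = frame.box
    # distance screen
    if crit.distance_convention == "O_to_H":
        d = minimum_image_table(pos[h_idx], pos[a_idx], box)
    else:
        d = minimum_image_table(pos[o_idx], pos[a_idx], box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    same_mol = frame.molecule_id[h_idx][:, None] == frame.molecule_id[a_idx][None, :]
    cand = np.argwhere((dist < crit.d_max) & ~same_mol)
    if cand.size == 0:
        return []
    hh = h_idx[cand[:, 0]]
    oo = o_idx[cand[:, 0]]
    aa = a_idx[cand[:, 1]]
    # angular cut: deviation from linearity of O-H...A at H
    if crit.angle_convention == "donor":
        # angle at donor O between the covalent O-H and O...acceptor
        v_oh = _mi_rows(pos[hh] - pos[oo], box)
        v_oa = _mi_rows(pos[aa] - pos[oo], box)
        cosv = np.einsum("ij,ij->i", v_oh, v_oa) / (
            np.linalg.norm(v_oh, axis=1) * np.linalg.norm(v_oa, axis=1))
        angle = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    else:
        # deviation from linearity of O-H...A, measured at the hydrogen
        v_ho = _mi_rows(pos[oo] - pos[hh], box)
        v_ha = _mi_rows(pos[aa] - pos[hh], box)
        cosv = np.einsum("ij,ij->i", v_ho, v_ha) / (
            np.linalg.norm(v_ho, axis=1) * np.linalg.norm(v_ha, axis=1))
        angle = 180.0 - np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    keep = angle < crit.angle_max
    records = []
    for o, h, a in zip(oo[keep], hh[keep], aa[keep]):
        w_d = frame.role[h] == ROLE_WATER
        w_a = frame.role[a] == ROLE_WATER
        cls = "WW" if (w_d and w_a) else ("CC" if not (w_d or w_a) else "CW")
        records.append(HBRecord(int(o), int(h), int(a), cls))
    return records


def _mi_rows(d, box):
    d = np.array(d, dtype=float)
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            d[:, ax] -= L * np.round(d[:, ax] / L)
    return d


def count_host_repeat_units(frame: SystemState) -> int:
    """Host repeat units, counted as host donor hydrogens (one hydroxyl
    decoration per repeat unit in the surrogate host)."""
    return int(np.sum(frame.donor_h & (frame.role != ROLE_WATER)))


def summarize_hbonds(records: List[HBRecord], frame: SystemState) -> HBSummary:
    """Normalized per-class counts for one frame.

    WW and CW are per water molecule; CC per host repeat unit. With no
    waters the per-water fields are NaN (dry state) while CC stays defined.
    """
    n_w = frame.n_water
    n_units = count_host_repeat_units(frame)
    n_ww = sum(1 for r in records if r.hb_class == "WW")
    n_cw = sum(1 for r in records if r.hb_class == "CW")
    n_cc = sum(1 for r in records if r.hb_class == "CC")
    summary = HBSummary(n_ww_raw=n_ww, n_cw_raw=n_cw, n_cc_raw=n_cc,
                        n_water=n_w, n_host_units=n_units)
    if n_units > 0:
        summary.hb_cc_per_unit = n_cc / n_units
    if n_w > 0:
        summary.hb_ww_per_water = n_ww / n_w
        summary.hb_cw_per_water = n_cw / n_w
        bound = set()
        for r in records:
            if r.hb_class != "CW":
                continue
            for i in (r.donor_h, r.acceptor):
                if frame.role[i] == ROLE_WATER:
                    bound.add(int(frame.molecule_id[i]))
        summary.fraction_water_bound_to_host = len(bound) / n_w
    return summary


def hb_energy(frame: SystemState, record: HBRecord) -> float:
    """Pair-isolation hydrogen-bond energy, kcal/mol (binding magnitude).

    The two bonded molecules are isolated (every other molecule removed)
    and their full intermolecular energy — 12-6 LJ plus *bare* (undamped,
    uncut) Coulomb at minimum image — is evaluated; the negative of that
    energy is returned as a positive binding magnitude.
    """
    mol_d = int(frame.molecule_id[record.donor_h])
    mol_a = int(frame.molecule_id[record.acceptor])
    if mol_d == mol_a:
        raise InvalidInputError("record references a single molecule")
    gi = frame.molecule_sites(mol_d)
    gj = frame.molecule_sites(mol_a)
    e = pair_intermolecular_energy(frame, gi, gj)
    return -e * KJ_TO_KCAL


def pair_intermolecular_energy(frame: SystemState, gi, gj) -> float:
    """Bare LJ + Coulomb energy (kJ/mol) between two site groups."""
    d = minimum_image_table(frame.positions[gi], frame.positions[gj], frame.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    qq = np.outer(frame.charge[gi], frame.charge[gj])
    e = float(np.sum(COULOMB_K * qq / r))
    eps = np.sqrt(np.outer(frame.epsilon[gi], frame.epsilon[gj]))
    if np.any(eps > 0):
        sig = 0.5 * (frame.sigma[gi][:, None] + frame.sigma[gj][None, :])
        sr6 = (sig / r) ** 6
        e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    return e


def mean_hb_energy(frames, hb_class: str = "WW", crit: HBCriterion = None,
                   max_bonds_per_frame: int = None, rng=None) -> float:
    """Trajectory-averaged pair-isolation binding energy (kcal/mol)."""
    vals = []
    for frame in frames:
        recs = [r for r in detect_hbonds(frame, crit) if r.hb_class == hb_class]
        if max_bonds_per_frame and len(recs) > max_bonds_per_frame:
            rng = rng or np.random.default_rng(0)
            recs = [recs[i] for i in
                    rng.choice(len(recs), max_bonds_per_frame, replace=False)]
        vals.extend(hb_energy(frame, r) for r in recs)
    if not vals:
        raise InvalidInputError(f"no {hb_class} hydrogen bonds found")
    return float(np.mean(vals))


# ----------------------------------------------------------------------
def hb_density_map(frames, hb_class: str, plane: str = "xy",
                   grid_resolution: int = 32, crit: HBCriterion = None):
    """Per-frame-normalized 2D histogram of bond midpoints.

    Midpoints of the donor-O ... acceptor segments of bonds of the given
    class, projected on ``plane`` ('xy', 'xz' or 'yz'); the map's total
    mass equals the mean bond count per frame.
    """
    if hb_class not in ("WW", "CW", "CC"):
        raise InvalidInputError(f"unknown HB class {hb_class!r}")
    axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    frames = list(frames)
    if not frames:
        raise InvalidInputError("empty trajectory")
    L = frames[0].box.lengths
    edges = [np.linspace(0, L[a], grid_resolution + 1) for a in axes]
    H = np.zeros((grid_resolution, grid_resolution))
    for frame in frames:
        pos = frame.wrapped_positions()
        for r in detect_hbonds(frame, crit):
            if r.hb_class != hb_class:
                continue
            d = _mi_rows((pos[r.acceptor] - pos[r.donor_o])[None, :], frame.box)[0]
            mid = (pos[r.donor_o] + 0.5 * d) % frame.box.lengths
            ix = min(int(mid[axes[0]] / L[axes[0]] * grid_resolution),
                     grid_resolution - 1)
            iy = min(int(mid[axes[1]] / L[axes[1]] * grid_resolution),
                     grid_resolution - 1)
            H[ix, iy] += 1.0
    return H / len(frames), edges


# ----------------------------------------------------------------------
@dataclass
class RadialDistribution:
    r: np.ndarray          # bin centers, nm
    g: np.ndarray          # dimensionless
    pair: tuple
    rho: float             # number density of the second species, nm^-3

    def coordination_number(self, r_min: float, r_max: float) -> float:
        """n = integral of 4 pi r^2 rho g(r) dr over [r_min, r_max]."""
        m = (self.r >= r_min) & (self.r <= r_max)
        return float(np.trapezoid(4.0 * np.pi * self.r[m] ** 2
                                  * self.rho * self.g[m], self.r[m]))


def compute_rdf(frames, pair, bins) -> RadialDistribution:
    """Species-pair radial distribution function with shell normalization.

    ``pair`` is a tuple of species labels, e.g. ``("OW", "HW")``;
    ``bins`` an array of bin edges (nm). Homogeneous-fluid normalization:
    g -> 1 at large r.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise InvalidInputError("bins must be increasing edges")
    frames = list(frames)
    la, lb = pair
    hist = np.zeros(bins.size - 1)
    norm = 0.0
    rho_b = 0.0
    for frame in frames:
        ia = np.flatnonzero(frame.species == la)
        ib = np.flatnonzero(frame.species == lb)
        if ia.size == 0 or ib.size == 0:
            continue
        d = minimum_image_table(frame.positions[ia], frame.positions[ib],
                                frame.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).ravel()
        if la == lb:
            r = r[r > 1e-9]
        else:
            same = (frame.molecule_id[ia][:, None]
                    == frame.molecule_id[ib][None, :]).ravel()
            r = r[~same]  # intermolecular structure only
        hist += np.histogram(r, bins=bins)[0]
        V = frame.box.volume
        rho_b += ib.size / V
        norm += ia.size * (ib.size if la != lb else ib.size - 1) / V
    nf = len(frames)
    rho_b /= max(nf, 1)
    shell = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    g = hist / (shell * norm) if norm > 0 else np.zeros_like(hist)
    centers = 0.5 * (bins[1:] + bins[:-1])
    return RadialDistribution(centers, g, tuple(pair), rho_b)


# ----------------------------------------------------------------------
def nww_scaling(points):
    """Log-log least-squares exponent of n_WW vs moisture content.

    ``points`` is a sequence of (m, n_ww_raw) with m > 0; returns
    (slope, stderr).
    """
    pts = [(m, n) for m, n in points if m > 0 and n > 0]
    if len(pts) < 4:
        raise InvalidInputError("need at least 4 positive points")
    x = np.log([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


@dataclass
class CapillaryShiftParams:
    D: float                 # pore size, nm
    Tc: float = 647.0        # bulk critical temperature, K
    lam: float = 0.28        # confined-molecule size, nm

    def __post_init__(self):
        if self.D <= 0 or self.Tc <= 0 or self.lam <= 0:
            raise InvalidInputError("capillary parameters must be positive")


def capillary_shift(p: CapillaryShiftParams) -> float:
    """Critical-point depression in a pore: T_c - T_cc = 4 lambda T_c / D."""
    return 4.0 * p.lam * p.Tc / p.D


def reversible_filling(p: CapillaryShiftParams, T_operating: float) -> bool:
    """True when T_cc <= operating temperature, i.e. pore filling at that
    temperature is reversible (no capillary hysteresis expected)."""
    return (p.Tc - capillary_shift(p)) <= T_operating
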