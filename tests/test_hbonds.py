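"""Hydrogen-bond detection, classification, energetics and structure
analysis tests."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sorpflex.builder import make_two_molecule
from sorpflex.hbonds import (CapillaryShiftParams, HBCriterion, HBRecord,
                             capillary_shift, compute_rdf, detect_hbonds,
                             hb_density_map, hb_energy, nww_scaling,
                             pair_intermolecular_energy, reversible_filling,
                             summarize_hbonds)
from sorpflex.model import (ROLE_HOST, ROLE_WATER, InvalidInputError,
                            SimulationBox, SystemState, empty_state)
from sorpflex.water import make_water

CRIT_H = HBCriterion(distance_convention="O_to_H", angle_convention="hydrogen")


def _frame_with_sites(positions, donor_h, acceptor, donor_o_of, mol_id,
                      role=None, L=5.0):
    n = len(positions)
    role = np.full(n, ROLE_WATER) if role is None else np.asarray(role)
    return SystemState(
        SimulationBox([L] * 3), positions,
        np.array(["OW" if a else "HW" for a in acceptor], object),
        np.where(acceptor, -0.8476, 0.4238), np.where(acceptor, 0.3166, 0.0),
        np.where(acceptor, 0.65, 0.0), np.where(acceptor, 16.0, 1.0),
        mol_id, role.astype(np.int8), donor_h=donor_h, acceptor=acceptor,
        donor_o_of=donor_o_of)


def _collinear_frame(acceptor_x, L=5.0):
    # donor O at origin, its H at (0.10, 0, 0), acceptor O at (x, 0, 0)
    pos = np.array([[0, 0, 0], [0.10, 0, 0], [acceptor_x, 0, 0]]) + L / 2
    return _frame_with_sites(pos, [False, True, False],
                             [True, False, True], [-1, 0, -1], [0, 0, 1], L=L)


def test_collinear_geometry_is_one_bond():
    recs = detect_hbonds(_collinear_frame(0.28), CRIT_H)
    assert len(recs) == 1
    assert recs[0].hb_class == "WW"


def test_distance_cut_rejects():
    assert detect_hbonds(_collinear_frame(0.50), CRIT_H) == []


def test_angle_cut_rejects():
    # acceptor at compliant distance but 45 degrees off the O-H axis at H
    ang = np.radians(45.0)
    r = 0.18
    pos = np.array([[0, 0, 0], [0.10, 0, 0],
                    [0.10 + r * np.cos(np.pi - ang) * -1,
                     r * np.sin(ang), 0]]) + 2.5
    fr = _frame_with_sites(pos, [False, True, False], [True, False, True],
                           [-1, 0, -1], [0, 0, 1])
    assert detect_hbonds(fr, CRIT_H) == []


def test_no_donors_gives_empty_list():
    st = empty_state(SimulationBox([3.0] * 3))
    assert detect_hbonds(st, CRIT_H) == []


@pytest.mark.parametrize("crit", [
    HBCriterion(),
    HBCriterion(distance_convention="O_to_H", angle_convention="hydrogen"),
    HBCriterion(distance_convention="O_to_O", angle_convention="hydrogen"),
])
def test_detection_matches_all_pairs_oracle(small_water_equil, crit):
    """Exact parity with an independent brute-force loop over every
    (donor H, acceptor) pair, for all criterion conventions."""
    frame = small_water_equil["frames"][0]
    got = {(r.donor_h, r.acceptor) for r in detect_hbonds(frame, crit)}
    L = frame.box.lengths

    def mi(v):
        return v - L * np.round(v / L)

    expect = set()
    for h in np.flatnonzero(frame.donor_h):
        o = frame.donor_o_of[h]
        for a in np.flatnonzero(frame.acceptor):
            if frame.molecule_id[a] == frame.molecule_id[h]:
                continue
            if crit.distance_convention == "O_to_H":
                d = np.linalg.norm(mi(frame.positions[a] - frame.positions[h]))
            else:
                d = np.linalg.norm(mi(frame.positions[a] - frame.positions[o]))
            if d >= crit.d_max:
                continue
            if crit.angle_convention == "donor":
                v1 = mi(frame.positions[h] - frame.positions[o])
                v2 = mi(frame.positions[a] - frame.positions[o])
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            else:
                v1 = mi(frame.positions[o] - frame.positions[h])
                v2 = mi(frame.positions[a] - frame.positions[h])
                ang = 180.0 - np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            if ang < crit.angle_max:
                expect.add((int(h), int(a)))
    assert got == expect


def test_summarize_two_waters_one_bond():
    fr = _collinear_frame(0.28)
    s = summarize_hbonds(detect_hbonds(fr, CRIT_H), fr)
    # frame holds 1 "water" of 3 sites? -> construct counts by hand:
    # 6 sites across 2 molecules is not a physical water pair here, so
    # check the raw count and normalization arithmetic instead
    assert s.n_ww_raw == 1


def test_summary_normalizations_and_additivity(small_water_equil):
    frame = small_water_equil["frames"][1]
    s = summarize_hbonds(detect_hbonds(frame), frame)
    n_w = frame.n_water
    assert s.hb_ww_per_water == pytest.approx(s.n_ww_raw / n_w, rel=1e-12)
    assert s.hb_total_per_water == pytest.approx(
        s.hb_ww_per_water + s.hb_cw_per_water, rel=1e-12, nan_ok=True)


def test_water_bound_only_to_host():
    # one water whose H donates to a host acceptor
    L = 5.0
    coords, params = make_water(np.array([2.5, 2.5, 2.5]),
                                np.array([1.0, 0, 0, 0]))
    st = empty_state(SimulationBox([L] * 3))
    st.add_water(coords, *params)
    # host acceptor placed collinear with one O-H bond
    oh = coords[1] - coords[0]
    acc = coords[1] + 0.18 * oh / np.linalg.norm(oh)
    st.positions = np.vstack([st.positions, acc])
    st.species = np.append(st.species, "OS")
    st.charge = np.append(st.charge, -0.8)
    st.sigma = np.append(st.sigma, 0.3166)
    st.epsilon = np.append(st.epsilon, 0.65)
    st.mass = np.append(st.mass, 16.0)
    st.molecule_id = np.append(st.molecule_id, 10)
    st.role = np.append(st.role, ROLE_HOST).astype(np.int8)
    st.donor_h = np.append(st.donor_h, False)
    st.acceptor = np.append(st.acceptor, True)
    st.donor_o_of = np.append(st.donor_o_of, -1)
    st.velocities = np.vstack([st.velocities, np.zeros(3)])
    st.invalidate_caches()
    s = summarize_hbonds(detect_hbonds(st), st)
    assert s.fraction_water_bound_to_host == 1.0
    assert s.hb_ww_per_water == 0.0


# ----------------------------------------------------------------------
# pair-isolation energies
# ----------------------------------------------------------------------

def test_distant_waters_have_zero_binding():
    st = make_two_molecule(separation=2.4, box_length=10.0)
    rec = HBRecord(donor_o=0, donor_h=1, acceptor=3, hb_class="WW")
    assert hb_energy(st, rec) == pytest.approx(0.0, abs=0.05)


def test_single_molecule_record_rejected(small_water_equil):
    frame = small_water_equil["frames"][0]
    g = frame.topology.rigid_groups[0]
    rec = HBRecord(donor_o=int(g[0]), donor_h=int(g[1]),
                   acceptor=int(g[0]), hb_class="WW")
    with pytest.raises(InvalidInputError):
        hb_energy(frame, rec)


def test_dimer_optimum_binding_matches_minimization_oracle():
    """Numerically minimize the rigid-water dimer energy surface. The
    3-site model with augmented charges binds its dimer at ~7.2 kcal/mol
    (stronger than the ~6.2-6.6 kcal/mol of the unaugmented 3-site and
    4-site models); the optimum must land in the 7.0-7.4 window and
    exceed the liquid-phase bond average."""
    from sorpflex.water import quaternion_to_matrix

    def energy(x):
        sep = x[0]
        q1 = x[1:5] / np.linalg.norm(x[1:5])
        q2 = x[5:9] / np.linalg.norm(x[5:9])
        st = make_two_molecule(separation=abs(sep), box_length=20.0,
                               orientation1=q1, orientation2=q2)
        gi = st.molecule_sites(0)
        gj = st.molecule_sites(1)
        return pair_intermolecular_energy(st, gi, gj)

    best = np.inf
    rng = np.random.default_rng(5)
    for _ in range(12):
        x0 = np.concatenate([[0.28 + 0.04 * rng.standard_normal()],
                             rng.standard_normal(4), rng.standard_normal(4)])
        res = minimize(energy, x0, method="Nelder-Mead",
                       options={"maxiter": 1200, "fatol": 1e-8})
        best = min(best, res.fun)
    binding_kcal = -best / 4.184
    assert 7.0 <= binding_kcal <= 7.4


# ----------------------------------------------------------------------
# density maps / rdf / scaling / capillary
# ----------------------------------------------------------------------

def test_density_map_single_bond_single_cell():
    fr = _collinear_frame(0.28)
    H, edges = hb_density_map([fr], "WW", plane="xy", grid_resolution=10,
                              crit=CRIT_H)
    assert np.count_nonzero(H) == 1
    assert H.sum() == pytest.approx(1.0)


def test_density_map_mass_is_mean_bond_count(small_water_equil):
    frames = small_water_equil["frames"][:3]
    H, _ = hb_density_map(frames, "WW", grid_resolution=16)
    counts = [sum(1 for r in detect_hbonds(f) if r.hb_class == "WW")
              for f in frames]
    assert H.sum() == pytest.approx(np.mean(counts), rel=1e-9)


def test_rdf_ideal_gas_is_unity(rng):
    n, L = 400, 5.0
    frames = []
    for k in range(6):
        pos = rng.random((n, 3)) * L
        frames.append(SystemState(
            SimulationBox([L] * 3), pos, np.array(["ID"] * n, object),
            np.zeros(n), np.zeros(n), np.zeros(n), np.ones(n),
            np.arange(n), np.zeros(n, np.int8)))
    rdf = compute_rdf(frames, ("ID", "ID"), np.arange(0.2, 2.0, 0.1))
    assert np.all(np.abs(rdf.g - 1.0) < 0.15)  # ~3 s.e. at these counts


def test_rdf_bad_bins_rejected(small_water_equil):
    with pytest.raises(InvalidInputError):
        compute_rdf(small_water_equil["frames"][:1], ("OW", "HW"),
                    np.array([0.2, 0.1]))


def test_nww_scaling_recovers_exponents(rng):
    m = np.linspace(0.02, 0.3, 8)
    slope, se = nww_scaling(list(zip(m, 7.0 * m ** 2)))
    assert slope == pytest.approx(2.0, abs=1e-9)
    slope, _ = nww_scaling(list(zip(m, 3.0 * m)))
    assert slope == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(InvalidInputError):
        nww_scaling([(0.1, 5.0)])


def test_capillary_shift_identities():
    assert capillary_shift(CapillaryShiftParams(D=1.12, Tc=647.0)) \
        == pytest.approx(647.0, rel=1e-12)
    assert capillary_shift(CapillaryShiftParams(D=0.28, Tc=647.0)) \
        == pytest.approx(4 * 647.0, rel=1e-12)
    s1 = capillary_shift(CapillaryShiftParams(D=1.0, Tc=647.0))
    s2 = capillary_shift(CapillaryShiftParams(D=2.0, Tc=647.0))
    assert s1 == pytest.approx(2 * s2, rel=1e-12)
    # sub-nm pores at room temperature: filling is reversible
    assert reversible_filling(CapillaryShiftParams(D=0.3, Tc=647.0), 300.0)
    with pytest.raises(InvalidInputError):
        CapillaryShiftParams(D=-1.0)
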