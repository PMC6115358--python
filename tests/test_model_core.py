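"""Unit tests for the molecular data model and energy terms."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from sorpflex.energy import (NonbondedSettings, bonded_energy_forces,
                             minimum_image, pair_energy, total_energy,
                             total_forces)
from sorpflex.model import (InvalidInputError, OverlapError, SimulationBox,
                            Site, SystemState, Topology, empty_state)
from sorpflex.units import COULOMB_K
from sorpflex.water import make_water, random_quaternion, water_dipole


def cubic_box(L=2.0):
    return SimulationBox([L, L, L])


# ----------------------------------------------------------------------
# minimum image
# ----------------------------------------------------------------------

@pytest.mark.parametrize("r1,r2,expect", [
    ((0, 0, 0), (1.8, 0, 0), (-0.2, 0, 0)),        # wrap-around, L=2
    ((0.3, 0.4, 0.5), (0.3, 0.4, 0.5), (0, 0, 0)),  # identity
])
def test_minimum_image_basic(r1, r2, expect):
    d = minimum_image(np.array(r1, float), np.array(r2, float), cubic_box(2.0))
    np.testing.assert_allclose(d, expect, atol=1e-12)


def test_minimum_image_half_box_tie_positive():
    d = minimum_image(np.zeros(3), np.array([1.0, 0, 0]), cubic_box(2.0))
    assert d[0] == pytest.approx(1.0)  # |d| = L/2, tie broken toward +L/2
    assert abs(d[0]) <= 1.0 + 1e-12


def test_minimum_image_rejects_non_finite():
    with pytest.raises(InvalidInputError):
        minimum_image(np.array([np.nan, 0, 0]), np.zeros(3), cubic_box())


@hyp_settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-10, 10), min_size=3, max_size=3),
       st.lists(st.floats(-10, 10), min_size=3, max_size=3))
def test_minimum_image_within_half_box(r1, r2):
    box = cubic_box(2.0)
    d = minimum_image(np.array(r1), np.array(r2), box)
    assert np.all(np.abs(d) <= 1.0 + 1e-9)


# ----------------------------------------------------------------------
# pair energy
# ----------------------------------------------------------------------

def _site(pos, q=0.0, sig=0.0, eps=0.0):
    return Site(np.array(pos, float), "X", charge=q, lj_sigma=sig,
                lj_epsilon=eps, mass=1.0)


def test_lj_minimum_depth():
    sig, eps = 0.3, 0.5
    r = 2 ** (1 / 6) * sig
    e = pair_energy(_site([0, 0, 0], sig=sig, eps=eps),
                    _site([r, 0, 0], sig=sig, eps=eps),
                    cubic_box(5.0), cutoff=2.0)
    assert e == pytest.approx(-eps, rel=1e-12)


def test_bare_coulomb_reference():
    # +e / -e at 1 nm; with a huge cutoff the shifted-force terms vanish
    e = pair_energy(_site([0, 0, 0], q=1.0), _site([1.0, 0, 0], q=-1.0),
                    SimulationBox([1e7] * 3), cutoff=1e6)
    assert e == pytest.approx(-COULOMB_K, rel=1e-5)
    assert e == pytest.approx(-138.935, abs=1e-3)


def test_beyond_cutoff_zero():
    e = pair_energy(_site([0, 0, 0], q=1, sig=0.3, eps=1.0),
                    _site([1.2, 0, 0], q=-1, sig=0.3, eps=1.0),
                    cubic_box(5.0), cutoff=0.9)
    assert e == 0.0


def test_overlap_raises():
    with pytest.raises(OverlapError):
        pair_energy(_site([0, 0, 0], eps=1.0, sig=0.3),
                    _site([1e-9, 0, 0], eps=1.0, sig=0.3), cubic_box())


# ----------------------------------------------------------------------
# total energy
# ----------------------------------------------------------------------

def _random_state(rng, n=50, L=3.0, charged=True):
    pos = rng.random((n, 3)) * L
    q = rng.normal(0, 0.3, n) if charged else np.zeros(n)
    q -= q.mean()
    return SystemState(
        cubic_box(L), pos, np.array(["X"] * n, object), q,
        np.full(n, 0.3), np.full(n, 0.4), np.ones(n),
        np.arange(n), np.zeros(n, np.int8))


def test_total_energy_empty_state():
    eb = total_energy(empty_state())
    assert eb.lj == eb.coulomb == eb.bonded == eb.total == 0.0


def test_total_energy_lj_dimer():
    sig, eps = 0.3, 0.7
    n = 2
    st_ = SystemState(cubic_box(5.0),
                      [[0, 0, 0], [2 ** (1 / 6) * sig, 0, 0]],
                      np.array(["A", "A"], object), np.zeros(n),
                      np.full(n, sig), np.full(n, eps), np.ones(n),
                      np.arange(n), np.zeros(n, np.int8))
    assert total_energy(st_, cutoff=2.0).total == pytest.approx(-eps, rel=1e-12)


def test_harmonic_bond_energy_convention():
    # E = k (r - r0)^2
    k, r0, delta = 1000.0, 0.5, 0.03
    topo = Topology(bonds=[[0, 1]], bond_k=[k], bond_r0=[r0])
    st_ = SystemState(cubic_box(5.0), [[0, 0, 0], [r0 + delta, 0, 0]],
                      np.array(["A", "A"], object), np.zeros(2), np.zeros(2),
                      np.zeros(2), np.ones(2), np.zeros(2, np.int64),
                      np.zeros(2, np.int8), topo)
    assert total_energy(st_).bonded == pytest.approx(k * delta ** 2, rel=1e-12)


def test_breakdown_total_identity(rng):
    st_ = _random_state(rng)
    eb = total_energy(st_, cutoff=0.9)
    assert eb.total == pytest.approx(eb.lj + eb.coulomb + eb.bonded, rel=1e-12)


def test_energy_translation_and_permutation_invariance(rng):
    st_ = _random_state(rng, n=50)
    e0 = total_energy(st_, cutoff=0.9).total
    shifted = st_.copy()
    shifted.positions += np.array([1.234, -0.77, 0.4])
    assert total_energy(shifted, cutoff=0.9).total == pytest.approx(e0, rel=1e-9)
    perm = rng.permutation(st_.n_sites)
    permuted = SystemState(
        st_.box.copy(), st_.positions[perm], st_.species[perm],
        st_.charge[perm], st_.sigma[perm], st_.epsilon[perm], st_.mass[perm],
        st_.molecule_id[perm], st_.role[perm])
    assert total_energy(permuted, cutoff=0.9).total == pytest.approx(e0, rel=1e-9)


def test_pair_energies_match_brute_force_oracle(rng):
    """Kernel total vs an independent double-loop evaluation (same physics,
    written separately) on a 120-site charged LJ system."""
    st_ = _random_state(rng, n=120, L=2.5)
    settings = NonbondedSettings(cutoff=0.9, dsf_alpha=0.0)
    e_lj_k, e_c_k, _, _ = __import__("sorpflex.energy", fromlist=["x"]) \
        .nonbonded_energy(st_, settings)
    rc = settings.cutoff
    e_lj = e_c = 0.0
    L = st_.box.lengths
    for i in range(st_.n_sites - 1):
        for j in range(i + 1, st_.n_sites):
            d = st_.positions[i] - st_.positions[j]
            d -= L * np.round(d / L)
            r = np.sqrt(d @ d)
            if r >= rc:
                continue
            sij = 0.5 * (st_.sigma[i] + st_.sigma[j])
            eij = np.sqrt(st_.epsilon[i] * st_.epsilon[j])
            sr6 = (sij / r) ** 6
            e_lj += 4 * eij * (sr6 ** 2 - sr6)
            e_c += COULOMB_K * st_.charge[i] * st_.charge[j] * (
                1 / r - 1 / rc + (r - rc) / rc ** 2)
    assert e_lj_k == pytest.approx(e_lj, rel=1e-9)
    assert e_c_k == pytest.approx(e_c, rel=1e-9)


# ----------------------------------------------------------------------
# forces
# ----------------------------------------------------------------------

def _bonded_test_state():
    topo = Topology(
        bonds=[[0, 1], [1, 2], [2, 3]], bond_k=[800, 900, 700],
        bond_r0=[0.4, 0.35, 0.45],
        angles=[[0, 1, 2], [1, 2, 3]], angle_k=[60.0, 80.0],
        angle_theta0=[np.radians(110), np.radians(120)],
        dihedrals=[(0, 1, 2, 3, [(5.0, 1, 0.0), (2.0, 3, np.pi / 2)])])
    pos = np.array([[0.1, 0.1, 0.0], [0.5, 0.15, 0.1],
                    [0.7, 0.45, 0.05], [1.05, 0.6, 0.3]])
    n = 4
    return SystemState(cubic_box(4.0), pos, np.array(["A"] * n, object),
                       np.array([0.2, -0.1, -0.3, 0.2]), np.full(n, 0.3),
                       np.full(n, 0.2), np.ones(n), np.zeros(n, np.int64),
                       np.zeros(n, np.int8), topo)


def test_newtons_third_law_and_finite_difference_forces():
    st_ = _bonded_test_state()
    settings = NonbondedSettings(cutoff=1.5)
    f, _, _ = total_forces(st_, settings)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)
    h = 1e-6
    for i in range(st_.n_sites):
        for a in range(3):
            for sgn, store in ((1, "p"), (-1, "m")):
                s2 = st_.copy()
                s2.positions[i, a] += sgn * h
                if sgn == 1:
                    ep = total_energy(s2, cutoff=1.5).total
                else:
                    em = total_energy(s2, cutoff=1.5).total
            f_fd = -(ep - em) / (2 * h)
            assert f[i, a] == pytest.approx(f_fd, rel=2e-4, abs=1e-4)


def test_bonded_exclusions_are_applied():
    # 1-2 and 1-3 neighbors contribute no nonbonded energy
    topo = Topology(bonds=[[0, 1], [1, 2]], bond_k=[0.0, 0.0],
                    bond_r0=[0.3, 0.3])
    n = 3
    st_ = SystemState(cubic_box(4.0),
                      [[0, 0, 0], [0.3, 0, 0], [0.6, 0, 0]],
                      np.array(["A"] * n, object), np.array([1.0, -2.0, 1.0]),
                      np.full(n, 0.3), np.full(n, 1.0), np.ones(n),
                      np.zeros(n, np.int64), np.zeros(n, np.int8), topo)
    eb = total_energy(st_, cutoff=1.5)
    assert eb.lj == 0.0 and eb.coulomb == 0.0


# ----------------------------------------------------------------------
# rigid water construction
# ----------------------------------------------------------------------

def test_make_water_geometry_and_neutrality():
    coords, (species, charge, *_rest) = make_water(
        np.zeros(3), np.array([1.0, 0, 0, 0]))
    d1 = np.linalg.norm(coords[1] - coords[0])
    d2 = np.linalg.norm(coords[2] - coords[0])
    assert abs(d1 - d2) < 1e-12
    assert d1 == pytest.approx(0.1, abs=1e-12)
    cos_hoh = ((coords[1] - coords[0]) @ (coords[2] - coords[0])) / (d1 * d2)
    assert np.degrees(np.arccos(cos_hoh)) == pytest.approx(109.47, abs=1e-9)
    assert charge.sum() == pytest.approx(0.0, abs=1e-12)


def test_water_dipole_rotates_with_quaternion(rng):
    q = random_quaternion(rng)
    from sorpflex.water import quaternion_to_matrix
    c0, _ = make_water(np.zeros(3), np.array([1.0, 0, 0, 0]))
    c1, _ = make_water(np.zeros(3), q)
    R = quaternion_to_matrix(q)
    np.testing.assert_allclose(water_dipole(c1), R @ water_dipole(c0),
                               atol=1e-12)


def test_unnormalized_quaternion_rejected():
    with pytest.raises(InvalidInputError):
        make_water(np.zeros(3), np.array([1.0, 1.0, 0, 0]))
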