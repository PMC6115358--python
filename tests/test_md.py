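"""Integrator tests: energy conservation, thermostats, constraints,
frozen-host contract, and virial stress."""

import numpy as np
import pytest

from sorpflex.builder import make_bulk_water, make_fixture
from sorpflex.energy import NonbondedSettings, total_energy, total_forces
from sorpflex.md import (IntegratorSpec, MDEngine, measure_stress,
                         minimize_energy, molecular_stress)
from sorpflex.model import ROLE_HOST, SimulationBox, SystemState
from sorpflex.units import INTERNAL_TO_PA, KB, INTERNAL_TO_GPA


def _lj_dimer(r=None):
    sig, eps = 0.3, 1.0
    r = r if r is not None else 2 ** (1 / 6) * sig * 1.02
    n = 2
    return SystemState(SimulationBox([4.0] * 3), [[1, 1, 1], [1 + r, 1, 1]],
                       np.array(["A", "A"], object), np.zeros(n),
                       np.full(n, sig), np.full(n, eps),
                       np.full(n, 20.0), np.arange(n), np.zeros(n, np.int8))


def test_nve_energy_conservation_lj_dimer():
    """Symplectic check: 10^4 1-fs steps drift < 1e-4 relative."""
    st = _lj_dimer()
    settings = NonbondedSettings(cutoff=1.5)
    spec = IntegratorSpec(dt=0.001, ensemble="NVE")
    eng = MDEngine(st, spec, settings=settings, rng=np.random.default_rng(1))
    e0 = total_energy(st, cutoff=1.5).total + eng.kinetic_energy()
    eng.run(10000)
    e1 = total_energy(st, cutoff=1.5).total + eng.kinetic_energy()
    scale = max(abs(e0), eng.kinetic_energy(), 1e-3)
    assert abs(e1 - e0) / scale < 1e-4


def test_nvt_equipartition_ideal_gas():
    n = 120
    rng = np.random.default_rng(5)
    st = SystemState(SimulationBox([5.0] * 3), rng.random((n, 3)) * 5,
                     np.array(["A"] * n, object), np.zeros(n), np.zeros(n),
                     np.zeros(n), np.full(n, 10.0), np.arange(n),
                     np.zeros(n, np.int8))
    eng = MDEngine(st, IntegratorSpec(T_target=300.0, ensemble="NVT"),
                   settings=NonbondedSettings(cutoff=0.5),
                   rng=np.random.default_rng(6))
    eng.initialize_velocities(250.0)
    temps = []
    for _ in range(60):
        eng.run(50)
        temps.append(eng.kinetic_temperature())
    t = np.array(temps[10:])
    k = 10
    b = t[:len(t) // k * k].reshape(k, -1).mean(axis=1)
    se = b.std(ddof=1) / np.sqrt(k)
    assert abs(t.mean() - 300.0) < 3 * max(se, 1.0)


def test_frozen_host_is_bit_identical(small_water_equil):
    st = make_fixture("slit_pore", gap=1.5, spacing=0.2)
    # drop a few waters in
    from sorpflex.gcmc import GCMCEngine, ReservoirSpec, run_gcmc_block
    res = ReservoirSpec(T=300.0, RH=0.9)
    eng_mc = GCMCEngine(st, res, np.random.default_rng(3))
    run_gcmc_block(st, res, 500, {"insert": 1.0}, engine=eng_mc)
    host = st.role == ROLE_HOST
    before = st.positions[host].copy()
    eng = MDEngine(st, IntegratorSpec(T_target=300.0, ensemble="NVT",
                                      thermostat="langevin"),
                   settings=NonbondedSettings(cutoff=0.6),
                   rng=np.random.default_rng(4))
    eng.initialize_velocities(300.0)
    eng.run(300)
    np.testing.assert_array_equal(st.positions[host], before)
    assert np.all(st.velocities[host] == 0.0)


def test_rigid_water_geometry_preserved(small_water_equil):
    st = small_water_equil["state"]
    for g in st.topology.rigid_groups[:10]:
        d_oh1 = np.linalg.norm(st.positions[g[0]] - st.positions[g[1]])
        d_oh2 = np.linalg.norm(st.positions[g[0]] - st.positions[g[2]])
        assert d_oh1 == pytest.approx(0.1, abs=1e-9)
        assert d_oh2 == pytest.approx(0.1, abs=1e-9)


def test_momentum_conservation(small_water_equil):
    st = small_water_equil["state"]
    p = (st.mass[:, None] * st.velocities).sum(axis=0)
    assert np.all(np.abs(p) < 1e-8)


def test_ideal_gas_stress():
    n = 150
    rng = np.random.default_rng(8)
    L = 4.0
    st = SystemState(SimulationBox([L] * 3), rng.random((n, 3)) * L,
                     np.array(["A"] * n, object), np.zeros(n), np.zeros(n),
                     np.zeros(n), np.full(n, 18.0), np.arange(n),
                     np.zeros(n, np.int8))
    eng = MDEngine(st, IntegratorSpec(T_target=300.0, ensemble="NVT",
                                      thermostat="langevin"),
                   settings=NonbondedSettings(cutoff=0.5),
                   rng=np.random.default_rng(9))
    eng.initialize_velocities(300.0)
    sigs = []
    for _ in range(40):
        eng.run(20)
        sigs.append(measure_stress(st, NonbondedSettings(cutoff=0.5)))
    sig = np.mean(sigs, axis=0)
    expect = -n * KB * 300.0 / st.box.volume * INTERNAL_TO_PA
    se = np.std([np.mean(s) for s in sigs]) / np.sqrt(len(sigs))
    for a in range(3):
        assert abs(sig[a] - expect) < 3 * max(3 * se, 0.05 * abs(expect))


def test_harmonic_solid_stress_zero_at_equilibrium():
    st = make_fixture("harmonic_solid", n_cells=3, a=0.4, k=500.0)
    sig = measure_stress(st, NonbondedSettings(cutoff=0.3))
    np.testing.assert_allclose(sig, 0.0, atol=1e-6)


def test_harmonic_solid_stress_matches_lattice_formula():
    """Uniform isotropic stretch: sigma = 2 k eps_l / a per axis (per-site
    one bond of rest length a per axis, E = k (dr)^2)."""
    a, k = 0.4, 500.0
    st = make_fixture("harmonic_solid", n_cells=3, a=a, k=k)
    eps_l = 0.01
    st.box.lengths *= (1 + eps_l)
    st.positions *= (1 + eps_l)
    sig = measure_stress(st, NonbondedSettings(cutoff=0.3))
    n_sites = st.n_sites
    V = st.box.volume
    # n_sites bonds along each axis, each stretched by a*eps_l,
    # tension f = 2 k a eps_l, lever arm ~ a (1 + eps_l)
    expect = n_sites * 2 * k * (a * eps_l) * a * (1 + eps_l) / V * INTERNAL_TO_PA
    np.testing.assert_allclose(sig, expect, rtol=1e-9)


def test_molecular_stress_matches_volume_perturbation(small_water_equil):
    """Independent oracle: configurational stress per axis equals the
    finite-difference derivative of energy under axis scaling with
    rigid-molecule COM displacement."""
    st = small_water_equil["state"].copy()
    st.velocities[:] = 0.0
    settings = small_water_equil["settings"]
    f, _, w = total_forces(st, settings)
    sig = molecular_stress(st, f, w)
    h = 1e-5
    for axis in range(3):
        es = []
        for s in (+h, -h):
            s2 = st.copy()
            mu = np.ones(3)
            mu[axis] = 1 + s
            s2.box.lengths *= mu
            for g in s2.topology.rigid_groups:
                m = s2.mass[g][:, None]
                com = (m * s2.positions[g]).sum(0) / m.sum()
                s2.positions[g] += com * (mu - 1.0)
            es.append(total_energy(s2, cutoff=settings.cutoff,
                                   dsf_alpha=settings.dsf_alpha).total)
        fd = (es[0] - es[1]) / (2 * h) / st.box.volume
        assert sig[axis] == pytest.approx(fd, rel=5e-4, abs=1e-3)


def test_nsigmat_water_density_bracket():
    """NsigmaT at 0 Pa / 300 K holds liquid rigid-3-site water in the
    0.94-1.05 g/cm^3 bracket (scaled-down statistical check)."""
    from sorpflex.units import density_g_cm3
    st = make_bulk_water(n=125, density=0.997, seed=3)
    settings = NonbondedSettings(cutoff=0.75)
    eng = MDEngine(st, IntegratorSpec(T_target=300.0, ensemble="NVT",
                                      thermostat="langevin",
                                      langevin_gamma=10.0),
                   settings=settings, rng=np.random.default_rng(21))
    eng.initialize_velocities(300.0)
    eng.run(6000)
    eng.spec = IntegratorSpec(T_target=300.0, ensemble="NsigmaT",
                              thermostat="langevin", langevin_gamma=5.0)
    vols = []
    for _ in range(40):
        eng.run(500)
        vols.append(st.box.volume)
    rho = density_g_cm3(st.mass.sum(), float(np.mean(vols[10:])))
    assert 0.94 <= rho <= 1.05


def test_minimizer_reduces_energy_of_clashed_pair():
    st = _lj_dimer(r=0.15)
    e0 = total_energy(st, cutoff=1.5).total
    e1 = minimize_energy(st, NonbondedSettings(cutoff=1.5), max_steps=500,
                         f_tol=1.0)
    assert e1 < e0 and e1 == pytest.approx(-1.0, abs=0.01)  # LJ minimum


def test_divergence_reports_stability_error():
    from sorpflex.md import StabilityError
    st = _lj_dimer(r=0.02)  # catastrophic overlap
    eng = MDEngine(st, IntegratorSpec(dt=0.05, ensemble="NVE"),
                   settings=NonbondedSettings(cutoff=1.5),
                   rng=np.random.default_rng(0))
    with pytest.raises(StabilityError):
        eng.run(50)
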