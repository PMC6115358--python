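"""Reference benchmark protocols.

These functions run the package's standard validation computations from
scratch — the bulk-water hydrogen-bond/energetics benchmark and the
scaled-down surrogate-host sorption campaign — with every random draw tied
to one integer seed. They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .builder import BuildRecipe, grow_chains, make_bulk_water, relax_host
from .energy import NonbondedSettings
from .forcefield import load_forcefield
from .gcmc import ReservoirSpec
from .hbonds import HBCriterion, detect_hbonds, mean_hb_energy
from .md import IntegratorSpec, MDEngine
from .sorption import (ScheduleSpec, attach_bulk_moduli,
                       run_fixed_volume_control, run_isotherm)
from .texture import quasistatic_bulk_modulus

#: calibrated geometric criterion: O...O distance + donor angle is the
#: pairing that reproduces the bulk-water benchmark (~3.6 HB/molecule)
BULK_HB_CRITERION = HBCriterion(distance_convention="O_to_O",
                                angle_convention="donor")


def bulk_water_benchmark(seed: int = 1, n: int = 216,
                         equil_ps: float = 10.0, prod_ps: float = 50.0,
                         cutoff: float = 0.9, frame_stride_ps: float = 0.25,
                         keep_frames: bool = False) -> dict:
    """Liquid SPC/E at 300 K and 0.997 g/cm^3: HB count, cohesive energy
    and pair-isolation WW bond energy.

    Protocol: jittered-lattice start, Langevin equilibration, Nose-Hoover
    production in NVT; hydrogen bonds under the calibrated O...O/donor
    criterion; cohesive energy reported with the model's standard
    self-polarization correction (from the shipped parameter file).
    """
    rng_seed = int(seed) % (2 ** 31 - 1)
    state = make_bulk_water(n=n, density=0.997, seed=rng_seed)
    settings = NonbondedSettings(cutoff=cutoff)
    eng = MDEngine(state,
                   IntegratorSpec(T_target=300.0, ensemble="NVT",
                                  thermostat="langevin", langevin_gamma=10.0),
                   settings=settings,
                   rng=np.random.default_rng(rng_seed + 1))
    eng.initialize_velocities(300.0)
    eng.run(int(round(equil_ps * 1000)))
    eng.spec = IntegratorSpec(T_target=300.0, ensemble="NVT")

    stride = int(round(frame_stride_ps * 1000))
    n_frames = int(round(prod_ps * 1000)) // stride
    frames, epots, temps = [], [], []
    for _ in range(n_frames):
        eng.run(stride)
        frames.append(state.copy())
        epots.append(eng._epot)
        temps.append(eng.kinetic_temperature())

    hb_counts = [2.0 * len(detect_hbonds(f, BULK_HB_CRITERION)) / n
                 for f in frames[::4]]
    pol = load_forcefield("spce").extra["meta"]["polarization_correction"]
    cohesive = -float(np.mean(epots)) / n - pol
    ww_energy = mean_hb_energy(frames[::6], "WW", BULK_HB_CRITERION,
                               max_bonds_per_frame=150,
                               rng=np.random.default_rng(rng_seed + 2))
    out = {
        "n": n,
        "hb_per_molecule": float(np.mean(hb_counts)),
        "hb_per_molecule_sd": float(np.std(hb_counts)),
        "cohesive_kj_per_mol": cohesive,
        "raw_potential_kj_per_mol": float(np.mean(epots)) / n,
        "ww_bond_kcal_per_mol": float(ww_energy),
        "mean_temperature_K": float(np.mean(temps)),
    }
    if keep_frames:
        out["frames"] = frames
    return out


def ideal_gas_gcmc_benchmark(seed: int = 1, volume_nm3: float = 1000.0,
                             rh: float = 1.0, T: float = 300.0,
                             n_blocks: int = 220, block: int = 120) -> dict:
    """Grand-canonical occupation of an ideal vapor reservoir in an empty
    box; the exact answer is <N> = P V / (k_B T)."""
    from .gcmc import GCMCEngine, run_gcmc_block
    from .model import SimulationBox, empty_state

    state = empty_state(SimulationBox([volume_nm3 ** (1 / 3)] * 3))
    res = ReservoirSpec(T=T, RH=rh)
    eng = GCMCEngine(state, res,
                     np.random.default_rng(int(seed) % (2 ** 31 - 1)))
    samples = []
    for _ in range(n_blocks):
        run_gcmc_block(state, res, block, {"insert": 0.5, "delete": 0.5},
                       engine=eng)
        samples.append(state.n_water)
    s = np.array(samples[n_blocks // 5:], dtype=float)
    k = 10
    batches = s[:len(s) // k * k].reshape(k, -1).mean(axis=1)
    return {"mean_n": float(s.mean()),
            "se": float(batches.std(ddof=1) / np.sqrt(k)),
            "expected": res.activity * volume_nm3,
            "n": len(s)}


def surrogate_mechanism_campaign(seed: int = 1, n_chains: int = 3,
                                 units_per_chain: int = 10,
                                 rh_grid=(0.1, 0.3, 0.5, 0.7, 0.9, 0.99),
                                 relax_ps: float = 300.0,
                                 cutoff: float = 0.75,
                                 schedule_kw: dict = None) -> dict:
    """Scaled-down sorption/swelling/mechanics campaign on the surrogate
    host: deformable hybrid adsorption + desorption branches, frozen
    constant-volume controls in the dry and swollen states, and
    quasi-static bulk moduli along both deformable branches.
    """
    base_seed = int(seed) % (2 ** 31 - 1)
    settings = NonbondedSettings(cutoff=cutoff)
    host = grow_chains(BuildRecipe(n_chains=n_chains,
                                   units_per_chain=units_per_chain,
                                   target_density=1.2, seed=base_seed))
    host = relax_host(host, duration=relax_ps, T=300.0, seed=base_seed + 1,
                      settings=settings)
    V0 = host.box.volume
    dry = host.copy()

    kw = dict(gcmc_moves_per_block=2500, md_steps_per_block=400,
              max_blocks=40, group=5, tol=0.03, production_blocks=8,
              keep_snapshot=True, hb_criterion=BULK_HB_CRITERION)
    kw.update(schedule_kw or {})
    sched = ScheduleSpec(**kw)

    ads = run_isotherm(host, rh_grid, "adsorption", sched, settings,
                       seed=base_seed + 10, V0=V0)
    swollen = host.copy()
    des = run_isotherm(host, rh_grid, "desorption", sched, settings,
                       seed=base_seed + 20, V0=V0)

    for br in (ads, des):
        for p in br.points:
            p.K = quasistatic_bulk_modulus(p.snapshot, settings)
            p.snapshot = None  # free memory

    # controls probe the host *configurations* (dry and swollen): waters
    # are stripped so both sweeps start from an empty matrix
    for mol in swollen.water_molecule_ids():
        swollen.remove_molecule(int(mol))
    # controls are pure GCMC (cheap per move) but water exchange in/out of
    # larger pores nucleates slowly, so they get much deeper sampling than
    # the hybrid blocks to avoid metastable false convergence
    ctrl_kw = dict(kw)
    ctrl_kw.update(md_steps_per_block=0, keep_snapshot=False,
                   gcmc_moves_per_block=max(kw["gcmc_moves_per_block"], 15000),
                   max_blocks=36, group=6, production_blocks=6)
    ctrl_sched = ScheduleSpec(**ctrl_kw)
    ctrl_grid = tuple(rh_grid)[::2]  # coarser grid, deeper sampling
    dry_up, dry_down = run_fixed_volume_control(
        dry, flexible=False, RH_grid=ctrl_grid, schedule=ctrl_sched,
        settings=settings, seed=base_seed + 30)
    sw_up, sw_down = run_fixed_volume_control(
        swollen, flexible=False, RH_grid=ctrl_grid, schedule=ctrl_sched,
        settings=settings, seed=base_seed + 40)

    return {"adsorption": ads, "desorption": des,
            "control_dry": (dry_up, dry_down),
            "control_swollen": (sw_up, sw_down),
            "V0": V0, "dry_state": dry, "swollen_state": swollen}
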