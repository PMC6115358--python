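"""The hybrid GCMC/MD osmotic-ensemble sorption driver.

At fixed (mu, sigma, T) the driver alternates grand-canonical water
exchange blocks with NsigmaT molecular-dynamics blocks, letting the host
deform while water sorbs; scanned over an RH grid in the adsorption and
desorption directions it produces the sorption/swelling isotherm branches
whose history dependence is the phenomenon under study. Constant-volume
controls (flexible or frozen host) provide the hysteresis-free baselines.

Each RH point inherits the previous point's configuration — chaining final
configurations is what makes the sweep history dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .energy import NonbondedSettings
from .gcmc import DEFAULT_MOVE_MIX, GCMCEngine, ReservoirSpec, run_gcmc_block
from .hbonds import HBCriterion, HBSummary, detect_hbonds, summarize_hbonds
from .md import IntegratorSpec, MDEngine
from .model import ROLE_WATER, InvalidInputError, SystemState
from .units import KB, M_WATER
from .texture import bulk_modulus, tensile_test, volume_strain

DEFAULT_RH_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.10), 2)) + (0.99,)


@dataclass
class ScheduleSpec:
    """Block schedule for one hybrid (mu, sigma, T) state point.

    Defaults: 2000 GCMC attempts alternating with 1000 MD steps (1 fs) per
    block; convergence when two consecutive ``group``-block means of both
    m and V differ by less than ``tol`` (relative), then
    ``production_blocks`` more blocks are averaged.
    """

    gcmc_moves_per_block: int = 2000
    md_steps_per_block: int = 1000
    max_blocks: int = 60
    group: int = 10
    tol: float = 0.02
    production_blocks: int = 10
    move_mix: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_MIX))
    dt: float = 0.001
    T: float = 300.0
    sigma_ext: np.ndarray = None          # Pa, tension positive
    thermostat: str = "langevin"
    hb_criterion: HBCriterion = field(default_factory=HBCriterion)
    collect_hb: bool = True
    keep_snapshot: bool = False
    m_floor: float = 5e-3                 # absolute floor for the m test

    def __post_init__(self):
        if self.sigma_ext is None:
            self.sigma_ext = np.zeros(3)
        self.sigma_ext = np.asarray(self.sigma_ext, float).reshape(3)


@dataclass
class SorptionPoint:
    RH: float
    m: float                      # g water / g dry host
    eps_V: float
    N_w: float
    hb: Optional[HBSummary]
    K: Optional[float] = None     # GPa
    n_blocks_to_converge: int = 0
    converged: bool = True
    se_m: float = 0.0
    V: float = math.nan
    snapshot: Optional[SystemState] = None

    def __post_init__(self):
        if self.m < 0:
            raise InvalidInputError("moisture content cannot be negative")
        if self.eps_V <= -1:
            raise InvalidInputError("eps_V must exceed -1")


@dataclass
class IsothermBranch:
    direction: str                        # adsorption | desorption
    points: List[SorptionPoint]
    realization_seed: int = 0

    def __post_init__(self):
        rh = [p.RH for p in self.points]
        diffs = np.diff(rh)
        if self.direction == "adsorption" and np.any(diffs <= 0):
            raise InvalidInputError("adsorption grid must increase strictly")
        if self.direction == "desorption" and np.any(diffs >= 0):
            raise InvalidInputError("desorption grid must decrease strictly")

    def to_records(self):
        out = []
        for p in self.points:
            rec = {"direction": self.direction, "RH": p.RH, "m": p.m,
                   "eps_V": p.eps_V, "N_w": p.N_w, "K_GPa": p.K,
                   "V_nm3": p.V, "converged": p.converged,
                   "n_blocks": p.n_blocks_to_converge, "se_m": p.se_m}
            if p.hb is not None:
                rec.update(hb_ww_per_water=p.hb.hb_ww_per_water,
                           hb_cw_per_water=p.hb.hb_cw_per_water,
                           hb_cc_per_unit=p.hb.hb_cc_per_unit,
                           n_ww_raw=p.hb.n_ww_raw,
                           fraction_bound=p.hb.fraction_water_bound_to_host)
            out.append(rec)
        return out


def _mean_hb(summaries: List[HBSummary]) -> Optional[HBSummary]:
    if not summaries:
        return None
    out = HBSummary()
    nanmean = lambda vals: (float(np.nanmean(vals))
                            if np.any(np.isfinite(vals)) else math.nan)
    out.hb_ww_per_water = nanmean([s.hb_ww_per_water for s in summaries])
    out.hb_cw_per_water = nanmean([s.hb_cw_per_water for s in summaries])
    out.hb_cc_per_unit = float(np.mean([s.hb_cc_per_unit for s in summaries]))
    out.n_ww_raw = float(np.mean([s.n_ww_raw for s in summaries]))
    out.n_cw_raw = float(np.mean([s.n_cw_raw for s in summaries]))
    out.n_cc_raw = float(np.mean([s.n_cc_raw for s in summaries]))
    out.fraction_water_bound_to_host = nanmean(
        [s.fraction_water_bound_to_host for s in summaries])
    out.n_water = float(np.mean([s.n_water for s in summaries]))
    out.n_host_units = summaries[0].n_host_units
    return out


def _thermalize_new_waters(state: SystemState, T: float, rng):
    """Give Maxwell-Boltzmann velocities to freshly inserted waters."""
    fresh = (state.role == ROLE_WATER) & (np.sum(state.velocities ** 2, axis=1) == 0)
    if not np.any(fresh):
        return
    sigma = np.sqrt(KB * T / state.mass[fresh])
    state.velocities[fresh] = rng.normal(size=(int(fresh.sum()), 3)) * sigma[:, None]


class HybridRunner:
    """Alternating GCMC / NsigmaT-MD runner bound to one state."""

    def __init__(self, state: SystemState, schedule: ScheduleSpec,
                 settings: NonbondedSettings = None, seed: int = 0,
                 constant_volume: bool = False):
        self.state = state
        self.schedule = schedule
        self.settings = settings or NonbondedSettings()
        self.rng = np.random.default_rng(seed)
        self.constant_volume = constant_volume
        ens = "NVT" if constant_volume else "NsigmaT"
        self.md_spec = IntegratorSpec(
            dt=schedule.dt, T_target=schedule.T, ensemble=ens,
            sigma_ext=schedule.sigma_ext, thermostat=schedule.thermostat)
        self.md = MDEngine(state, self.md_spec, settings=self.settings,
                           rng=self.rng)

    def run_block(self, reservoir: ReservoirSpec, gcmc_engine: GCMCEngine):
        sch = self.schedule
        run_gcmc_block(self.state, reservoir, sch.gcmc_moves_per_block,
                       sch.move_mix, engine=gcmc_engine)
        if sch.md_steps_per_block > 0 and self.state.n_sites > 0:
            _thermalize_new_waters(self.state, sch.T, self.rng)
            self.md.run(sch.md_steps_per_block)

    def run_point(self, reservoir: ReservoirSpec, V0: float = None):
        """Equilibrate then average one (mu, sigma, T) state point."""
        sch = self.schedule
        st = self.state
        gcmc = GCMCEngine(st, reservoir, self.rng, self.settings)
        if V0 is None:
            V0 = st.box.volume
        prev_group = None
        block_m, block_v = [], []
        converged = False
        n_run = 0
        while n_run < sch.max_blocks:
            self.run_block(reservoir, gcmc)
            n_run += 1
            block_m.append(st.moisture_content if st.dry_mass > 0 else
                           st.n_water * M_WATER)
            block_v.append(st.box.volume)
            if n_run % sch.group == 0:
                g_m = float(np.mean(block_m[-sch.group:]))
                g_v = float(np.mean(block_v[-sch.group:]))
                if prev_group is not None:
                    dm = abs(g_m - prev_group[0])
                    dv = abs(g_v - prev_group[1]) / max(prev_group[1], 1e-12)
                    if dm <= max(sch.tol * abs(prev_group[0]), sch.m_floor) \
                            and dv <= sch.tol:
                        converged = True
                        break
                prev_group = (g_m, g_v)
        # production
        prod_m, prod_v, prod_n, hb_list = [], [], [], []
        for _ in range(sch.production_blocks):
            self.run_block(reservoir, gcmc)
            prod_m.append(st.moisture_content if st.dry_mass > 0 else
                          st.n_water * M_WATER)
            prod_v.append(st.box.volume)
            prod_n.append(st.n_water)
            if sch.collect_hb:
                recs = detect_hbonds(st, sch.hb_criterion)
                hb_list.append(summarize_hbonds(recs, st))
        m = float(np.mean(prod_m))
        V = float(np.mean(prod_v))
        se_m = float(np.std(prod_m, ddof=1) / np.sqrt(len(prod_m))) \
            if len(prod_m) > 1 else 0.0
        point = SorptionPoint(
            RH=reservoir.RH, m=max(m, 0.0),
            eps_V=volume_strain(V, V0), N_w=float(np.mean(prod_n)),
            hb=_mean_hb(hb_list), n_blocks_to_converge=n_run,
            converged=converged, se_m=se_m, V=V,
            snapshot=st.copy() if sch.keep_snapshot else None)
        return point


def run_hybrid_point(state: SystemState, reservoir: ReservoirSpec,
                     schedule: ScheduleSpec = None,
                     settings: NonbondedSettings = None, seed: int = 0,
                     V0: float = None, constant_volume: bool = False):
    """One (mu, sigma, T) state point; returns (state, SorptionPoint)."""
    schedule = schedule or ScheduleSpec()
    runner = HybridRunner(state, schedule, settings, seed, constant_volume)
    point = runner.run_point(reservoir, V0=V0)
    return state, point


def run_isotherm(initial_state: SystemState, RH_grid, direction: str,
                 schedule: ScheduleSpec = None,
                 settings: NonbondedSettings = None, seed: int = 0,
                 T: float = 300.0, V0: float = None,
                 constant_volume: bool = False) -> IsothermBranch:
    """Sweep an RH grid in one direction, chaining configurations.

    ``initial_state`` is modified in place (the final state seeds a
    subsequent sweep, e.g. desorption starting from the swollen
    near-saturation state).
    """
    if direction not in ("adsorption", "desorption"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    grid = sorted(RH_grid) if direction == "adsorption" \
        else sorted(RH_grid, reverse=True)
    schedule = schedule or ScheduleSpec(T=T)
    if V0 is None:
        V0 = initial_state.box.volume
    runner = HybridRunner(initial_state, schedule, settings, seed,
                          constant_volume)
    points = []
    for rh in grid:
        res = ReservoirSpec(T=schedule.T, RH=float(rh))
        points.append(runner.run_point(res, V0=V0))
    return IsothermBranch(direction, points, realization_seed=seed)


def run_fixed_volume_control(state: SystemState, flexible: bool, RH_grid,
                             schedule: ScheduleSpec = None,
                             settings: NonbondedSettings = None,
                             seed: int = 0):
    """Constant-volume adsorption/desorption control cycle.

    The box volume is held at the input state's value throughout; with
    ``flexible=False`` the host is additionally frozen (pure GCMC between
    water moves). Returns (up_branch, down_branch) for the hysteresis
    comparison.
    """
    st = state.copy()
    st.frozen_host = not flexible
    schedule = schedule or ScheduleSpec()
    if not flexible:
        schedule = replace(schedule, md_steps_per_block=0)
    up = run_isotherm(st, RH_grid, "adsorption", schedule, settings,
                      seed=seed, V0=st.box.volume, constant_volume=True)
    down = run_isotherm(st, RH_grid, "desorption", schedule, settings,
                        seed=seed + 1, V0=st.box.volume, constant_volume=True)
    return up, down


def attach_bulk_moduli(branch: IsothermBranch, linear_window=(0.0, 0.02),
                       eps_max: float = 0.04, duration_ns: float = 0.002,
                       settings: NonbondedSettings = None, seed: int = 0,
                       T: float = 300.0) -> IsothermBranch:
    """Run a volumetric tensile test on each point's snapshot and store the
    extracted undrained bulk modulus (requires ``keep_snapshot=True``)."""
    for p in branch.points:
        if p.snapshot is None:
            raise InvalidInputError("points carry no snapshots; rerun the "
                                    "sweep with keep_snapshot=True")
        curve = tensile_test(p.snapshot, eps_max=eps_max,
                             duration_ns=duration_ns, T=T,
                             settings=settings, seed=seed)
        p.K = bulk_modulus(curve, linear_window)[0]
    return branch
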