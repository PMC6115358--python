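"""Textural and mechanical analysis: pore-size distributions, volume
strain, the volumetric tensile test, and bulk-modulus extraction.

The PSD uses the stochastic largest-inscribed-sphere construction: for
random test points in the void, the pore diameter at a point is the
diameter of the largest sphere that contains the point while overlapping
no site, with sites inflated by the probe van der Waals radius (0.1 nm by
default). The histogram over test points is the geometric pore-diameter
distribution.

The tensile test imposes a linear volumetric strain ramp (eps_V from 0 to
0.1 over the run, isotropic box rescaling) under constant-moisture MD;
the small-strain slope of mean stress vs eps_V is the undrained bulk
modulus K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .energy import NonbondedSettings
from .md import IntegratorSpec, MDEngine, StabilityError
from .model import InvalidInputError, SystemState
from .units import INTERNAL_TO_GPA


@dataclass
class PSDHistogram:
    diameters: np.ndarray        # bin centers, nm
    density: np.ndarray          # probability density, nm^-1
    probe_vdw_radius: float
    n_sample_points: int
    empty: bool = False          # True when no void exists at this probe

    @property
    def mode(self) -> float:
        return float(self.diameters[np.argmax(self.density)])

    def mean_diameter(self) -> float:
        w = self.density / self.density.sum() if self.density.sum() else self.density
        return float(np.sum(self.diameters * w))


def compute_psd(frame: SystemState, probe_vdw_radius: float = 0.1,
                n_samples: int = 2000, seed: int = 0,
                n_centers: int = 20000, bin_width: float = 0.05,
                d_max: float = None) -> PSDHistogram:
    """Stochastic largest-inscribed-sphere pore-size distribution.

    Random candidate sphere centers are drawn in the cell; each has radius
    R(c) = (distance to nearest site) - probe radius. A test point's pore
    diameter is the largest 2R(c) over candidates whose sphere contains
    it. Periodic images are included via a KD-tree on a 3x3x3 tiling.
    """
    if probe_vdw_radius < 0:
        raise InvalidInputError("probe radius must be non-negative")
    rng = np.random.default_rng(seed)
    L = frame.box.lengths
    if d_max is None:
        d_max = float(np.min(L))
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    centers_of_bins = 0.5 * (edges[1:] + edges[:-1])

    if frame.n_sites == 0:
        # empty periodic cell: largest inscribed sphere has diameter min(L)
        density = np.zeros(edges.size - 1)
        i = np.searchsorted(edges, float(np.min(L))) - 1
        i = min(max(i, 0), density.size - 1)
        density[i] = 1.0 / bin_width
        return PSDHistogram(centers_of_bins, density, probe_vdw_radius,
                            n_samples)

    pos = frame.wrapped_positions()
    images = []
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                images.append(pos + np.array([sx, sy, sz]) * L)
    tree = cKDTree(np.vstack(images))

    cand = rng.random((n_centers, 3)) * L
    R = tree.query(cand, k=1)[0] - probe_vdw_radius
    keep = R > 0
    cand, R = cand[keep], R[keep]

    test = rng.random((n_samples, 3)) * L
    r_test = tree.query(test, k=1)[0] - probe_vdw_radius
    void = r_test > 0
    if not np.any(void) or cand.size == 0:
        return PSDHistogram(centers_of_bins, np.zeros(edges.size - 1),
                            probe_vdw_radius, n_samples, empty=True)
    test = test[void]
    best = np.maximum(tree.query(test, k=1)[0] - probe_vdw_radius, 0.0)
    # chunked max over candidates containing each test point
    for tlo in range(0, len(test), 512):
        t = test[tlo:tlo + 512]
        b = best[tlo:tlo + 512]
        for lo in range(0, len(cand), 8192):
            c = cand[lo:lo + 8192]
            r = R[lo:lo + 8192]
            d = t[:, None, :] - c[None, :, :]
            d -= L * np.round(d / L)
            inside = np.einsum("ijk,ijk->ij", d, d) <= r[None, :] ** 2
            masked = np.where(inside, r[None, :], 0.0)
            np.maximum(b, masked.max(axis=1), out=b)
    hist, _ = np.histogram(2.0 * best, bins=edges)
    total = hist.sum()
    density = hist / (total * bin_width) if total else hist.astype(float)
    return PSDHistogram(centers_of_bins, density, probe_vdw_radius,
                        len(test), empty=(total == 0))


def volume_strain(V: float, V0: float) -> float:
    """eps_V = V/V0 - 1 (swelling relative to the dry reference)."""
    if V0 <= 0:
        raise InvalidInputError("reference volume must be positive")
    return V / V0 - 1.0


@dataclass
class StressStrainCurve:
    eps_v: np.ndarray        # dimensionless, nondecreasing
    sigma: np.ndarray        # GPa, mean normal stress, tension positive
    strain_rate: float       # ns^-1
    duration: float          # ns
    truncated: bool = False

    def __post_init__(self):
        self.eps_v = np.asarray(self.eps_v, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.eps_v.shape != self.sigma.shape:
            raise InvalidInputError("eps_V and sigma must have equal length")
        if np.any(np.diff(self.eps_v) < -1e-12):
            raise InvalidInputError("eps_V samples must be nondecreasing")


def tensile_test(state: SystemState, eps_max: float = 0.1,
                 duration_ns: float = 0.05, T: float = 300.0,
                 settings: NonbondedSettings = None, seed: int = 0,
                 dt: float = 0.001, sample_every: int = 10,
                 thermostat: str = "langevin",
                 equilibration_steps: int = 200) -> StressStrainCurve:
    """Volumetric tensile test at constant temperature and moisture.

    The box is rescaled isotropically every step so eps_V(t) follows a
    linear ramp from 0 to ``eps_max``; stress is recorded continuously.
    No GCMC runs during loading (undrained conditions). The input state is
    not modified.
    """
    st = state.copy()
    spec = IntegratorSpec(dt=dt, T_target=T, ensemble="NVT",
                          thermostat=thermostat)
    eng = MDEngine(st, spec, settings=settings,
                   rng=np.random.default_rng(seed))
    if not np.any(np.abs(st.velocities) > 0):
        eng.initialize_velocities(T)
    eng.run(equilibration_steps)
    n_steps = max(int(round(duration_ns * 1000.0 / dt)), sample_every)
    eps_samples, sig_samples = [0.0], []
    sig0 = eng.internal_stress()
    sig_samples.append(float(np.mean(sig0)) * INTERNAL_TO_GPA)
    eps_prev = 0.0
    truncated = False
    try:
        for step in range(1, n_steps + 1):
            eps = eps_max * step / n_steps
            mu = ((1.0 + eps) / (1.0 + eps_prev)) ** (1.0 / 3.0)
            eng._scale_box(np.full(3, mu))
            eps_prev = eps
            eng.run(1)
            if step % sample_every == 0:
                sig = eng.internal_stress()
                eps_samples.append(eps)
                sig_samples.append(float(np.mean(sig)) * INTERNAL_TO_GPA)
    except StabilityError:
        truncated = True
    n = min(len(eps_samples), len(sig_samples))
    duration = duration_ns
    return StressStrainCurve(np.array(eps_samples[:n]),
                             np.array(sig_samples[:n]),
                             strain_rate=eps_max / duration_ns,
                             duration=duration, truncated=truncated)


def quasistatic_bulk_modulus(state: SystemState,
                             settings: NonbondedSettings = None,
                             eps_range: float = 0.01, n_points: int = 7,
                             quench: bool = True,
                             quench_steps: int = 600) -> float:
    """Quasi-static (affine, energy-curvature) undrained bulk modulus, GPa.

    After an optional energy quench, the configuration is scaled
    *affinely* (rigid molecules by center of mass) to a handful of
    volumes around the reference and K = V0 d^2U/dV^2 is taken from a
    quadratic fit of the energy-volume curve. This is the Born
    (instantaneous) elastic term: deterministic, smooth, and suitable for
    comparing stiffness across sorption states on desk-scale systems
    where a thermal stress ramp is noise-dominated. Moisture content is
    fixed throughout (undrained).
    """
    from .md import minimize_energy
    from .energy import total_energy
    settings = settings or NonbondedSettings()
    ref = state.copy()
    ref.velocities[:] = 0.0
    if quench:
        minimize_energy(ref, settings, max_steps=quench_steps, f_tol=50.0)
    V0 = ref.box.volume
    eps = np.linspace(-eps_range, eps_range, n_points)
    vols, energies = [], []
    for e in eps:
        s = ref.copy()
        mu = (1.0 + e) ** (1.0 / 3.0)
        s.box.lengths *= mu
        scaled = np.zeros(s.n_sites, dtype=bool)
        for g in s.topology.rigid_groups:
            m = s.mass[g][:, None]
            com = (m * s.positions[g]).sum(0) / m.sum()
            s.positions[g] += com * (mu - 1.0)
            scaled[g] = True
        s.positions[~scaled] *= mu
        vols.append(s.box.volume)
        energies.append(total_energy(s, cutoff=settings.cutoff,
                                     dsf_alpha=settings.dsf_alpha).total)
    c = np.polyfit(np.asarray(vols) - V0, np.asarray(energies), 2)
    return float(2.0 * c[0] * V0 * INTERNAL_TO_GPA)


def bulk_modulus(curve: StressStrainCurve, linear_window=(0.0, 0.02)):
    """Undrained bulk modulus: least-squares slope of sigma vs eps_V over
    the small-strain window. Returns (K in GPa, standard error)."""
    lo, hi = linear_window
    m = (curve.eps_v >= lo) & (curve.eps_v <= hi)
    if int(np.sum(m)) < 5:
        raise InvalidInputError("linear window holds fewer than 5 samples")
    res = stats.linregress(curve.eps_v[m], curve.sigma[m])
    return float(res.slope), float(res.stderr if np.isfinite(res.stderr) else 0.0)
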