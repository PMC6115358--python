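# Methods

`sorpflex` simulates water sorption in a deformable nanoporous polymer in
the osmotic (μσT) ensemble by alternating grand-canonical Monte Carlo
(GCMC) water exchange with isothermal–isostress (NσT) molecular dynamics,
and provides the analysis stack — hydrogen-bond networks and energies,
pore-size distributions, swelling strain, and bulk moduli — needed to
dissect sorption–swelling hysteresis. This note records the model, the
numerical choices, and what the desk-scale surrogate can and cannot show.

## Ensembles and the hybrid cycle

A sorption state point fixes the water chemical potential μ, the external
stress σ on the host, and temperature T. The water reservoir is an ideal
vapor: relative humidity maps to chemical potential through
μ − μ₀ = k_B T ln RH, anchored at the saturation pressure of the SPC/E
water model at 300 K, P₀ = 1017 Pa, so the insertion activity is
z = RH·P₀/(k_B T). RH = 0 is treated as the dry limit (no insertions;
deletions always accepted, the z → 0 limit of the delete weight), not as
a finite μ.

GCMC moves are standard Metropolis: insertion at a uniform position with
a uniform random orientation, deletion of a uniform random water,
rigid-body translation and rotation. Acceptance weights are
zV/(N+1)·e^(−βΔU) for insertion, N/(zV)·e^(−βΔU) for deletion, e^(−βΔU)
otherwise; no configurational-bias or cavity-bias moves are used, so
acceptance at high density is earned by the MD relaxation between blocks.
Host sites are never proposed by GCMC.

A hybrid block is `gcmc_moves_per_block` attempts (default 2000) followed
by `md_steps_per_block` NσT steps (default 1000 at 1 fs). Block means of
moisture content m and volume V are grouped (default groups of 10); a
point is converged when two consecutive group means agree within 2%
(with an absolute floor of 0.005 on m), after which production blocks
(default 10) are averaged. Isotherm sweeps chain the final configuration
of each RH point into the next — this history dependence is the
mechanism under study, so it is deliberate, and the desorption branch
starts from the final adsorption state near saturation.

## Interactions

Nonbonded interactions are 12-6 Lennard-Jones with Lorentz–Berthelot
mixing, truncated (unshifted) at the cutoff, plus damped-shifted-force
(DSF) Coulomb evaluated at the minimum image. The damping parameter
defaults to α = 0 — the undamped shifted-force limit of the DSF family —
with a 0.9 nm cutoff; α is a plain parameter for users who want the
damped variant. This real-space scheme was chosen over Ewald summation
for desk-scale speed; the hysteresis mechanism probed here does not hinge
on k-space accuracy, and the choice is recorded in run manifests. No
long-range dispersion tail corrections are applied (documented omission).
Bonded terms are class-I: harmonic bonds and angles with the
`E = k·Δ²` convention stated in the parameter files, plus a cosine
dihedral series. 1-2 and 1-3 nonbonded pairs are excluded.

Water is rigid 3-site SPC/E; its geometry and charges are loaded from
`data/spce.ff`, never hard-coded. Rigidity is enforced by constraint
projection — the three distance constraints of each water are solved exactly each step by batched 3×3 Newton iterations (positions) and linear
solves (velocities), holding O–H distances to ~1e-12 nm and permitting
1 fs steps.

## Integrator, thermostat, barostat

The MD core is velocity-Verlet. Temperature control is a Nosé–Hoover
chain (length 2, relaxation time 500 fs) for production; a Langevin
thermostat is the robust fallback used for equilibrating fresh builds and
melted lattices, where a Nosé–Hoover chain removes the large latent heat
of structural relaxation too slowly. Stress control is a weak-coupling
(Berendsen-style) anisotropic barostat: each box length relaxes
independently toward its external stress with a 2 ps time constant and a
per-step scale clamp of 0.5%; rigid molecules are rescaled by their
centers of mass. A full Nosé–Hoover/MTK barostat with constraints was
judged unnecessary at desk scale, since only the relaxed stress state —
not the volume-fluctuation spectrum — enters the method.

Stress uses the molecular (rigid-group) virial: the atomic virial is
corrected to group centers of mass and the kinetic term of rigid groups
uses COM velocities. This form needs no constraint-force bookkeeping and
is validated in the tests against a finite-difference volume-perturbation
oracle (agreement to ~1e-4 relative). Sign convention: tension positive,
so an ideal gas has diagonal stress −Nk_BT/V.

Positions are stored unwrapped; wrapped views are computed for analysis
(PSD, density maps). New waters inserted by GCMC receive
Maxwell–Boltzmann velocities at the start of the next MD block.

## Hydrogen bonds

A hydrogen bond is a donor O–H paired with an acceptor O on a different
molecule, with a 0.35 nm distance cutoff and a 30° angular cutoff. Both
the distance and angle conventions vary in the literature, so both are
first-class and recorded in outputs:

* distance: donor-O···acceptor (`O_to_O`, default) or H···acceptor
  (`O_to_H`);
* angle: at the donor oxygen between the covalent O–H and the
  O···acceptor vector (`donor`, default), or the deviation from
  linearity of O–H···A measured at the hydrogen (`hydrogen`).

The default pairing (O···O < 0.35 nm, donor angle < 30°) is the
calibrated criterion: on bulk SPC/E water at 300 K it reproduces the
standard benchmark of ≈3.6 hydrogen bonds per molecule, whereas the
looser H-distance variant over-counts and the stricter at-H-angle
variant under-counts relative to that benchmark.
Bonds are classed WW (water–water), CW (host–water, either direction)
and CC (host–host); WW and CW are normalized per water molecule, CC per
host repeat unit, and the additivity HB_total = HB^WW + HB^CW holds by
construction.

Pair-isolation bond energies remove every other molecule and evaluate
the full intermolecular energy of the bonded pair — 12-6 LJ plus *bare*
(undamped, uncut) Coulomb at minimum image — reported as a positive
binding magnitude in kcal/mol (conversion fixed at 4.184). The rigid
SPC/E dimer optimum computed this way is ≈7.2 kcal/mol; the liquid-phase
trajectory average over detected WW bonds is ≈4.5 kcal/mol.

Cohesive energy of the liquid is reported as −⟨U⟩/N minus the SPC/E
self-polarization correction (5.22 kJ/mol per molecule, stored in
`spce.ff [meta]`); this is the model's standard accounting for comparing
with experiment-like cohesive energies (~40 kJ/mol), while the raw
−⟨U⟩/N this package measures for SPC/E is ≈44.5 kJ/mol.

## Surrogate host

The host is a bead-spring stand-in for amorphous cellulose: chains of
repeat units, each unit a heavy backbone bead (CB) plus a hydroxyl pair
(OS, HS) with water-like charges (−0.8/+0.4, CB +0.4 for neutrality), so
every unit both donates and accepts hydrogen bonds. "Per repeat unit"
plays the role of "per glucopyranose ring" in CC normalization. The CB
diameter (0.45 nm) is chosen so that the relaxed glass packs densely
enough that its interstices are smaller than a water molecule — water
uptake must then open volume, which is the sorption–swelling coupling the
method exists to probe. The hydroxyl hydrogen carries a small LJ core:
unlike rigid water's H, a flexible bare charge would collapse onto
neighboring acceptors.

Hosts are grown as self-avoiding random walks packed to 1.2 g/cm³ (the
standard initial packing density for amorphous-cellulose builds), then
relaxed: capped-displacement steepest descent to remove growth contacts,
a short strongly-coupled Langevin startup, and NσT dynamics at 300 K /
0 Pa. The relaxed glass densifies well above the build density (the
surrogate's mass-to-volume mapping is not meant to reproduce cellulose's
absolute density); the campaign default of 300 ps of relaxation is the
point where residual volume drift falls below the ±2% fluctuation band
of these small cells — shorter preparations leave an aging drift that
masks sorption-induced swelling. Three independent realizations
(consecutive seeds) are the default for averaging, with s.d. error bars.

## Mechanics

The volumetric tensile test rescales the box isotropically so ε_V = V/V₀−1
follows a linear ramp (default 0 → 0.1) under constant-moisture MD,
recording stress continuously; the undrained bulk modulus K is the
least-squares slope of mean stress vs ε_V at small strain (default window
ε_V ≤ 0.02). On desk-scale systems (10²–10³ sites) the instantaneous
stress noise is of GPa order, so the campaign instead uses a quasi-static
estimator: quench the configuration, scale it affinely (rigid molecules
by COM) to a few volumes around the reference, and take K = V₀·d²U/dV²
from a quadratic fit. This Born (instantaneous) modulus is deterministic
and exact on the analytic harmonic-lattice oracle (K = 2k/(3a) for the
E = kΔ² spring convention); it is used for *comparisons across sorption
states*, where only monotone structure matters.

## Pore-size distribution

The PSD is the stochastic largest-inscribed-sphere construction: for
random test points in the void, the pore diameter at a point is the
largest 2R over random candidate sphere centers c with
R(c) = (distance to nearest site) − r_probe that contain the point, with
the probe van der Waals radius defaulting to 0.1 nm. Periodic images are
handled with a KD-tree on a 3×3×3 tiling. A constrained-optimization PSD
refinement was deliberately not implemented; the stochastic construction
converges to the same geometric distribution and its sampling noise is
controlled by the candidate/test counts. An empty periodic cell reports
all mass at the largest inscribed sphere of the cell (diameter min L).

## Scaled-down study conditions

The bulk-water benchmark uses 216 SPC/E molecules at 0.997 g/cm³,
10 ps Langevin equilibration and 50 ps Nosé–Hoover production at 300 K
with the 0.9 nm cutoff; hydrogen-bond statistics are computed on frames
every 1 ps and pair energies on a capped subsample of bonds.

The surrogate campaign defaults to 3 chains × 10 units (90 host sites),
a 6-point RH grid (0.1–0.99) per direction, blocks of 2500 GCMC attempts
+ 400 MD steps, up to 40 blocks to converge and 8 production blocks.
The frozen fixed-volume controls (pure GCMC, dry and swollen host
configurations with waters stripped) get much deeper per-point sampling
(15000 attempts per block) because water exchange in and out of frozen
pores nucleates slowly and shallow sampling registers metastable false
convergence.

These sizes resolve several *directions* of the
sorption–swelling–mechanics coupling — the hysteresis sign of the
deformable run, the hysteresis-free dry control, the larger uptake of
the swollen host, the HB^CC decrease with moisture and its
adsorption/desorption asymmetry, and the better organization of K
against HB^CC than against m — but not magnitudes, and three observables
remain out of the surrogate's desk-scale reach:

* the frozen *swollen* control keeps an up/down gap (~0.02–0.05 in m):
  its ~0.5–0.8 nm pores exchange water clusters bound by tens of kJ/mol
  through single-molecule GCMC moves, and the gap closes only
  logarithmically with move count;
* the ε_V–m collapse: the surrogate's sorption-induced swelling (+1–2%)
  has the same magnitude as the glassy aging/fluctuation band (±2–3%) of
  a 90-site cell over ~100 ps state points, so the strain signal is
  drift-dominated;
* sorption-induced weakening of K: the Born modulus of a bead-spring
  glass *stiffens* as pores fill (added LJ contacts outweigh lost
  host–host hydrogen bonds), the opposite of the atomistic HB-dominated
  weakening.

Quantitative isotherms, 36%-scale swelling and kcal-resolved CW
energetics require cluster-scale atomistic systems. Desorption kinetics
at desk scale are dominated by deep water traps (deletion acceptance
~e^(−β|U|)), which exaggerates retention relative to a fully
equilibrated branch; the qualitative asymmetry between branches is the
meaningful observable.

## Degenerate inputs and tie-breaks

Minimum image breaks the exact half-box tie toward +L/2. Empty systems
are valid everywhere (zero energies, empty HB lists, dry-limit sorption
points); deletion from an empty reservoir is a flagged rejection, not an
error. Overlapping interacting sites raise an overlap error in
`pair_energy` but contribute a large finite penalty (1e30 kJ/mol) in MC
kernels so acceptance is exactly zero. Dihedral forces are skipped for
degenerate collinear geometries (|b×b'|² < 1e-12). The RH = 0 reservoir
has μ = −∞ by construction and is reported as such.

## Known limitations

* Real-space electrostatics only (no Ewald backend yet; α and the cutoff
  are declared, not fitted).
* Weak-coupling barostat: correct relaxed states, approximate volume
  fluctuations (do not use its Var(V) for compressibility estimates).
* The surrogate host is not cellulose: no ring geometry, no PCFF class-II
  cross terms, bead-level hydroxyl chemistry only.
* Quasi-static K is a Born modulus; thermal softening is not included.
* PSD is geometric (probe-inflated), not a constrained-optimization fit.
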