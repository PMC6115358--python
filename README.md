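# sorpflex

Hybrid GCMC/MD simulation of water sorption in deformable nanoporous
polymers, with the analysis stack needed to dissect sorption–swelling
hysteresis: hydrogen-bond networks and energies, pore-size distributions,
swelling strain, and bulk moduli.

## The problem

Soft nanoporous polymers — amorphous cellulose being the canonical
example — swell as they take up water, and both the moisture content
*m* (grams of water per gram of dry host) and the volume strain
ε_V = V/V₀ − 1 show large hysteresis between adsorption and desorption.
Neither rigid-host grand-canonical Monte Carlo (no deformation, no
hysteresis) nor plain molecular dynamics (no open water reservoir)
can capture this: the phenomenon lives in the *osmotic (μσT) ensemble*,
where the water chemical potential μ, the external stress σ on the host
and the temperature T are fixed while both the water content and the
host volume fluctuate.

`sorpflex` implements that ensemble as a hybrid cycle: blocks of
grand-canonical water exchange (insert/delete/translate/rotate with
standard Metropolis weights, insertion weight zV/(N+1)·e^(−βΔU) with
z = RH·P₀/k_BT) alternate with isothermal–isostress (NσT) molecular
dynamics that lets the host relax and deform. Relative humidity maps to
chemical potential through the ideal-vapor relation
μ − μ₀ = k_B T ln RH, anchored at the SPC/E saturation pressure
P₀ = 1017 Pa at 300 K. Sweeping RH up and then down, with each state
point inheriting the previous configuration, produces the
adsorption/desorption branches whose history dependence is the object of
study; constant-volume flexible/frozen control sweeps provide the
hysteresis-free baselines.

The package is desk-scale by design: water is rigid 3-site SPC/E
(constraint projection, 1 fs steps), the host is a bead-spring
"cellulose surrogate" whose repeat units carry hydroxyl donor/acceptor
sites, and electrostatics is damped-shifted-force real-space Coulomb.
See `docs/methods.md` for the model, defaults and limitations.

## Worked example

Hydrogen bonding in bulk liquid water — the calibration that anchors the
sorption analysis:

```python
from sorpflex.benchmarks import bulk_water_benchmark

res = bulk_water_benchmark(seed=1, n=216, prod_ps=50.0)
print(f"HB per molecule : {res['hb_per_molecule']:.2f}")
print(f"cohesive energy : {res['cohesive_kj_per_mol']:.1f} kJ/mol")
print(f"E(HB_WW)        : {res['ww_bond_kcal_per_mol']:.2f} kcal/mol")
```

prints (seed 1):

```
HB per molecule : 3.57
cohesive energy : 39.4 kJ/mol
E(HB_WW)        : 4.55 kcal/mol
```

i.e. each water donates/accepts ≈3.6 hydrogen bonds under the geometric
criterion (O···O < 0.35 nm, donor angle < 30°), the liquid's cohesive
energy is ≈40 kJ/mol (with the SPC/E polarization accounting), and
isolating each hydrogen-bonded pair and averaging its bare LJ+Coulomb
interaction over the trajectory gives ≈4.5 kcal/mol per water–water bond.

A scaled-down sorption campaign on the surrogate host:

```python
from sorpflex.benchmarks import surrogate_mechanism_campaign

out = surrogate_mechanism_campaign(seed=1)
for p in out["adsorption"].points:
    print(f"RH={p.RH:.2f}  m={p.m:.3f}  eps_V={p.eps_V:+.3f}  "
          f"HB_CC={p.hb.hb_cc_per_unit:.2f}  K={p.K:.1f} GPa")
```

Desorption retains more water than adsorption at matched RH, host–host
hydrogen bonds break as moisture rises (and rebalance differently on the
two branches), and the frozen swollen host takes up more water than the
frozen dry one — the mechanism-level signatures of sorption–swelling
coupling at surrogate scale. `docs/methods.md` details which observables
the scaled-down surrogate resolves and which need cluster-scale
atomistic systems.

The same drivers are scriptable from the shell:

```bash
sorpflex build    --recipe host.toml --out host
sorpflex relax    --config host.toml --structure host.extxyz --out relaxed.extxyz
sorpflex isotherm --config run.toml --direction both
sorpflex controls --config run.toml --frozen
sorpflex analyze-hb --traj run.extxyz --criterion o_to_o
sorpflex psd      --frame relaxed.extxyz --probe 0.1
sorpflex tensile  --config run.toml
sorpflex report   --branch adsorption.csv --branch desorption.csv
```

Every run writes a `manifest.json` with the config hash, seeds and
forcefield checksums.

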