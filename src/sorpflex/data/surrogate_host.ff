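# Bead-spring surrogate polymer host ("cellulose surrogate").
# One repeat unit = 3 beads: CB backbone bead, OS hydroxyl oxygen,
# HS hydroxyl hydrogen. The unit is charge neutral; the OS/HS pair carries
# water-like hydroxyl charges so it donates and accepts hydrogen bonds.
# Energy conventions: E_bond = k*(r-r0)^2 ; E_angle = k*(theta-theta0)^2
[atoms]
# label  mass      charge   sigma   epsilon
# HS carries a small LJ core: unlike rigid water's H (shielded by its
# oxygen's geometry), a flexible hydroxyl H with bare charge would
# collapse onto neighboring acceptors.
# CB sigma is chosen so a repeat unit's excluded volume at the 1.2 g/cm^3
# packing density gives a glass-like packing fraction (~0.5), leaving
# small intrinsic voids rather than collapsing.
# Cohesion is deliberately hydrogen-bond dominated (hydroxyl charges
# +-0.9) with modest CB dispersion, mirroring a polar polymer whose
# stiffness is carried by its interchain HB network; a stiff backbone
# suppresses glassy aging drift at desk-scale run lengths.
CB       130.0      0.40    0.450   0.60
OS       15.9994   -0.80    0.3166  0.650
HS       1.00794    0.40    0.158   0.08
[bonds]
# i      j    k(kJ/mol/nm^2)  r0(nm)
CB       CB   10000.0         0.50
CB       OS   15000.0         0.24
OS       HS   20000.0         0.10
[angles]
# i      j    k    k(kJ/mol/rad^2)  theta0(deg)
CB       OS   HS   150.0            109.47
CB       CB   OS   100.0            109.47
CB       CB   CB   75.0             150.0
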