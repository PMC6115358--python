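# SPC/E rigid 3-site water.
# Energy conventions: E_bond = k*(r-r0)^2 ; E_angle = k*(theta-theta0)^2
# Units: mass g/mol, charge e, sigma nm, epsilon kJ/mol, k kJ/mol/nm^2 or
# kJ/mol/rad^2, r0 nm, theta0 degrees.
[atoms]
# label  mass      charge   sigma   epsilon
OW       15.9994   -0.8476  0.3166  0.650
HW       1.00794    0.4238  0.0     0.0
[rigid]
# rigid 3-site geometry (enforced by constraint projection, not springs)
r_oh          0.1
theta_hoh_deg 109.47
[meta]
# polarization self-energy correction of the effective pair model, kJ/mol
# per molecule; subtracted when reporting cohesive energies against
# experiment-like values.
polarization_correction 5.22
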