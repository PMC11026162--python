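# Solvent registry.
#
# eps_r     : relative permittivity at 25 C
# eta_cp    : dynamic viscosity in centipoise (alcohol values as used for the
#             conductivity -> ionic-strength correction)
# phi0_v    : default interfacial solvation potential in volts, signed.
#             Negative for water (interfacial molecular dipole points away from
#             the surface), positive for ethanol / isopropanol (dipole
#             inverted, methyl groups toward the surface).  The magnitude is an
#             effective model input; the per-solvent interfacial amplitude
#             calibration absorbs it.
water:
  eps_r: 78.5
  eta_cp: 0.89
  phi0_v: -0.15
ethanol:
  eps_r: 24.5
  eta_cp: 1.1
  phi0_v: 0.10
ipa:
  eps_r: 19.9
  eta_cp: 2.4
  phi0_v: 0.13
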