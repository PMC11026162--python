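# Surface-chemistry presets: ionizable-group type and effective single-site pK.
#
# site_density_per_m2 is an *effective* density of regulating groups; for the
# scenario presets shipped with the package it is overridden by the value the
# scenario calibration derives (see electrosolv.scenarios).
silica:
  group_type: acid
  pK: 6.0          # effective single-site value for silanol (true spectrum 2-11)
  site_density_per_m2: 3.5e15
cooh:
  group_type: acid
  pK: 4.5
  site_density_per_m2: 4.0e15
nh2:
  group_type: base
  pK: 9.5
  site_density_per_m2: 4.0e15
pss:
  group_type: acid
  pK: 3.0
  site_density_per_m2: 4.0e15
poly_e:
  group_type: acid
  pK: 4.5
  site_density_per_m2: 4.0e15
poly_k:
  group_type: base
  pK: 10.0
  site_density_per_m2: 4.0e15
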