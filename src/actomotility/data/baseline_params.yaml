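# Baseline parameter set of the coupled-myosin model (version 1).
#
# These numbers are a calibrated reconstruction, not published values: the
# baseline was fixed once so that simulated gliding reproduces the
# experimentally typical behaviour of smooth-muscle myosin propelling actin
# at 30 degC -- sliding velocity in the sub-um/s range, motile fraction
# rising steeply with filament length and saturating near 1, run times
# growing with length, and a stopped/running velocity structure resolvable
# at the 1/3 s analysis time step.  See docs/methods.md for the calibration
# rationale and the known limitations of this reconstruction.
version: 1
params:
  k_attach: 10.0       # 1/s per free site while the filament is tethered
  k_reengage: 0.2      # 1/s per site, first attachment to a released filament
  k_stroke: 1000.0     # 1/s, unstrained main power stroke (elastically gated)
  k_detach: 185.0      # 1/s, unstrained secondary step + detachment
  c_coupling: 1.0      # dimensionless coupling impact
  d_main_nm: 6.0       # main working-stroke distance
  d_second_nm: 4.0     # secondary step distance
  kappa_pn_nm: 2.0     # crossbridge stiffness (rigor-like)
  sigma_attach_nm: -1.0  # <0: thermal spread sqrt(kT/kappa) ~ 1.45 nm
  site_spacing_um: 0.0355
  kT_pn_nm: 4.186      # thermal energy at 30 degC
  noise_sigma_nm: 10.0 # positional measurement noise at sampling
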