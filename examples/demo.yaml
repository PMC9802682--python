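# Endoscopic demo: white-matter-tract phantom imaged through a rotating probe.
phantom:
  type: wmt
  size: [64, 64, 64]
  n_tracts: 3
  voxel_pitch: [12.0, 12.0, 12.0]
geometry:
  mode: helical
  n_revolutions: 3
  rotation_rate: 50.0        # rev/s
  pullback_speed: 1.0        # mm/s
  aline_rate: 25600.0        # A-lines/s -> 512 A-lines per revolution
  depth_pixels: 96
  delta_z: 4.8               # um
  probe_od: 870.0            # um (2.6 Fr)
  cannula_point: [384.0, 384.0, -60.0]
  cannula_axis: [1.0, 0.0, 0.0]
measurement:
  lambda_c: 1300.0           # nm
  sweep_range: 110.0         # nm
  n_tissue: 1.35
  snr_db: 35.0
  n_spectral_bins: 3
  system:
    random: {scale: 0.4}
  catheter:
    ret_mean: 0.3
    ret_amp: 0.2
    axis_amp: 0.3
  sheath:
    dn: 1.0e-3
    thickness_px: 4
    reflectivity: 1.0
reconstruction:
  kernel: [3, 3]
  dop_kernel: [5, 5]
  dop_threshold: 0.7
  axis_reference: sheath
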