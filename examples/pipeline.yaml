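# End-to-end synthetic demo configuration.
seed: 1
out_dir: runs/demo
radius: 3000.0
k: auto
k_max: 8
gap_B: 20
routing_algorithm: d8
synthetic:
  seed: 1
  grid_shape: [64, 64]
  cell_size: 150.0
  n_sites: 30
  trophic_offset_d13C: 0.35
  trophic_offset_d15N: 3.1
  noise_sd_d13C: 0.5
  noise_sd_d15N: 0.5
  frac_qc_fail: 0.09
  frac_infant: 0.05
qc:
  cn_min: 2.9
  cn_max: 3.6
  yield_min: 1.0
  pctC_min: 13.0
  pctN_min: 4.8
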