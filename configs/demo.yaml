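# Two-condition synthetic demo: an "organized control" versus a regime with
# looser clusters and faster calcium kinetics. All data are generated from
# the master seed; rerunning with the same seed reproduces summary.json
# byte for byte.
seed: 20260925
window_nm: 2000.0
n_replicates: 4
conditions:
  control:
    clusters:
      n_parents: 20
      offspring_mean: 25
      cluster_sigma: 20.0
      background_rate: 5.0e-06
    calcium:
      diastolic: 1.0
      systolic: 1.8
      rise_time: 0.1
      tau: 0.4
      noise_sd: 0.02
      duration: 20.0
  treated:
    clusters:
      n_parents: 20
      offspring_mean: 25
      cluster_sigma: 60.0
      background_rate: 5.0e-06
    calcium:
      diastolic: 1.0
      systolic: 1.8
      rise_time: 0.06
      tau: 0.25
      noise_sd: 0.02
      duration: 20.0
ripley:
  r_max: 300.0
  step: 5.0
  edge_mode: torus
persistence:
  max_radius: 150.0
  subsample: 400
nna:
  bin_width: 5.0
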