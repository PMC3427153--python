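# Default full-pipeline configuration: simulate the standard cohort
# (26 exposed / 17 unexposed / 14 reference tumors on a 10,000-probe map)
# and run normalization, HMM inference, calling, recurrence detection and
# the exposure-group comparison.  Replace the `simulate` block with an
# `inputs` block (probe_map / intensities / design / annotation paths) to
# analyze real arrays.
seed: 1

simulate:
  n_probes: 10000
  cohort: {exposed: 26, unexposed: 17, reference: 14}
  noise: {affinity_sigma: 0.25, array_scale_sigma: 0.3, noise_sigma: 0.1}
  # omit `segments` to use the four bundled exposure-differential gains

normalization:
  rank_threshold: 0.02
  min_set_size: 100
  max_iterations: 30
  curve_window_frac: 0.01

hmm:
  emission_sigma: 0.35
  event_rate: 0.1
  decay_length: 1000000
  window: 3

calling:
  gain_threshold: 2.8
  loss_threshold: 1.2
  min_run: 3

recurrence:
  min_fraction: 0.15
  min_probes: 3

significance:
  alpha: 0.05
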