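# Demo pipeline configuration: a small synthetic cohort that runs end to end
# in well under a minute. Scale n_animals, shape, density and the select
# block up for realistic experiments.
out_dir: catfish_demo
seed: 7
n_animals: 4
structures: [VTA, CA3]
conditioned: c3
synth:
  shape: [160, 160]
  n_layers: 7
  density: 0.00055        # ~12 nuclei per z-layer in the demo ROI
  p_first: 0.30
  p_second: 0.25
  rho_recent: 0.0
  rho_remote: 0.4         # remote group re-activates the same sub-population
  dot_count_mean: 3.0
  noise: [2.0, 1.0]
behavior:
  duration_s: 120
  dt_s: 0.2
  bias: {c3: 3.0}
select:
  n_repeats: 2
  n_trees: 50
  max_iter: 8
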