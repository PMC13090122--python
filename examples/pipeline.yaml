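# Full synthetic ceiling analysis: ~10 min on one CPU core.
#   ppgage pipeline --config examples/pipeline.yaml --out runs/exp1
seed: 0
k_folds: 5
cohort:
  n: 2000
  seed: 0
  # defaults reproduce the published ASI calibration; uncomment to explore
  # signal_strength: 0.0     # null cohort: no age signal at all
  # dispersion_sigma: 0.0    # noise-free ASI law
models:
  - {name: mean_baseline, kind: mean}
  - {name: asi_linear, kind: linear}
  - {name: asi_gam, kind: gam}
  - {name: smolk, kind: smolk}
  - {name: resnet, kind: resnet, params: {train: {max_epochs: 80}}}
group_size: 6
n_groups: 2
projection_neighbors: 15
projection_subsample: 1000
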