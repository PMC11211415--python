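# Desk-scale pipeline configuration for the `tmstraj run` CLI subcommand.
#   tmstraj run --config examples/pipeline_config.yaml --out my_run
# Study-scale settings would be n_starts: 100, g_max: 8, max_iter: 1000.
simulate:
  n_subjects: 80
  seed: 5
g_max: 3
n_starts: 6
max_iter: 1000
conv_b: 1.0e-4
conv_l: 1.0e-4
conv_g: 1.0e-4
min_class_fraction: 0.05
weekly_subsample: false
n_band_draws: 100
seed: 5
out_dir: tmstraj_run
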