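# Small demonstration run (minutes, one CPU). The config schema and the
# full-scale defaults are documented in oipr.pipeline.PipelineConfig.
out_dir = "runs/demo"

[simulate]
n_blocks = 12
n_neurons = 24
seed = 11

[binning]
bin_width = 250.0
bin_step = 100.0
delay_span = [0.0, 1050.0]
feedback_span = [-200.0, 600.0]

[decode]
n_per_condition = 25
k_folds = 5
n_resamples = 4
n_shuffles = 3
null_resamples = 2
min_consecutive = 3
seed = 12

[windows]
min_trials_per_condition = 20
n_resamples = 3
n_shuffles = 2
null_resamples = 2
k_folds = 4
seed = 13

[balanced]
n_resamples = 4
n_shuffles = 10
seed = 14

[geometry]
n_per_condition = 25
n_resamples = 30
min_consecutive = 3
seed = 15

[encode]
seed = 16

[stages]
windows = false
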