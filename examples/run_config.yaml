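# Example run configuration for `finbeat run --config examples/run_config.yaml`.
# Omitted keys take the documented defaults; every stage seed derives
# from the single master seed.

seed: 1
outdir: finbeat_results

# input: simulate sessions (set `manifest:` instead to use existing CSVs)
n_sessions: 4
session_length: 600.0     # seconds per session
include_rare: false       # also emit 'other' / 'out_of_camera' events

# features
epoch_seconds: [1, 2]
smoothing_window: 5       # samples, centred moving average
energy_form: magnitude    # or: squared

# ethogram
alpha: 0.05
merge_swim: auto          # auto | always | never

# modelling
models: [CART, RF, SVM, XGB, C50, GBM, NNET, AVNNET]
train_fraction: 0.8
tuning_profile: fast      # fast | full
cv_folds: 10
importance_repeats: 10
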