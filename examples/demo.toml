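# Reference study: 85 patients, 68/17 chronological split, planted
# heterogeneity contrast of 2.5x for short survivors.
seed = 1

[cohort]
n_patients = 85
train_fraction = 0.8
event_rate = 0.3
volume_effect = 1.2
heterogeneity_effect = 2.5
seed = 1

[signature]
n_folds = 5
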