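# Default synthetic cohort: published size and event count, 12 hospitals.
schema: default
n_patients: 3997
n_events: 176
n_hospitals: 12
shift_scale: 0.15
seed: 0
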