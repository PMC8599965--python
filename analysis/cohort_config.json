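{
    "outdir": "results/cohort_run",
    "seed": 20,
    "n_control": 22,
    "n_case": 24,
    "n_channels": 12,
    "n_timepoints": 305,
    "tr": 2.0,
    "n_states": 4,
    "n_restarts": 2,
    "density": 0.2,
    "n_null_graphs": 100,
    "n_perm": 1000
}
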