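# Experiment-1 style simulation + analysis configuration.
# Any ObserverParams field may be overridden under `observer:`.
experiment_id: E1
n_subjects: 31
titrate: true
fast_cutoff_s: 0.25   # robust fast-response filter (seconds); null disables
min_correct: 2        # subjects with fewer correct trials in any cell are dropped
min_cell_n: 10        # cells below this trial count are excluded from EZ fits
n_seeds: 3            # replicate cohorts for the `recover` command
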