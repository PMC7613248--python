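# Small end-to-end example: one noiseless replicate, quick stability pass.
simulate_scenario: noiseless
n_replicates: 1
reps: 50
distance_threshold: 0.6
seed: 17
run_name: example
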