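# Full-pipeline configuration for the synthetic experiment generated by
# analysis/01_simulate_experiment.py. All seeds are explicit.
input_dir: data/experiment
output_dir: results/pipeline
seed: 11
n_reps: 100
n_permutations: 1000
k: 7
linkage: complete
abundance_threshold: 0.01
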