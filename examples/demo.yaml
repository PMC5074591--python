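# Demo run configuration: all stages, small synthetic cohort.
# Run with:  metabomr pipeline --config examples/demo.yaml
seed: 4
out_dir: demo_run
n_individuals: 1000
n_metabolites: 10
theta: -0.4
score: insulin_resistance
min_rt: 35.0
dup_corr: 0.5
outlier_sd: 3.0
fdr_q: 0.05
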