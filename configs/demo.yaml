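# Demo pipeline configuration: six planted co-prescription communities,
# 20,000 prescriptions, published-marginal cohort at 20% scale.
# Run with:  chmnet --config configs/demo.yaml all
seed: 42
out_dir: chmnet-out
n_prescriptions: 20000
n_cohort_scale: 0.2
min_support: 1.0
min_confidence: 15.0
min_lift: 1.0
top_n: 100
cluster_method: greedy
ob_min: 0.30
dl_min: 0.18
ob_units: fraction
alpha: 0.05
correction: fdr_bh
n_proteins: 10000
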