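# Type I error grid under disease-related differential uptake:
# 20% withdrawal in the standard-test arm, screened prevalence halved there.
# Run: pairscreen simulate --grid examples/type1_differential.yaml --out type1.tsv
m_per_arm: [5000]
prev_a: [0.01]
prev_ratio: [0.5]
sens_b: [0.95]
specificity: [0.90, 0.95, 0.99]
odds_ratio: [1.0, 2.0, 5.0]
margins: [0.90, 0.95, 1.0]
uptake_a: 1.0
uptake_b: 0.8
reps: 2000
seed: 1
tests: [wald, score, lr]
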