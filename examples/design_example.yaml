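# Sample-size planning: noninferiority at margin 0.9, equal sensitivities
# under the alternative, 1% screened prevalence, perfect uptake.
# Run: pairscreen design --spec examples/design_example.yaml
delta0: 0.9
delta1: 1.0
sens_b: 0.95
or_diseased: 1.0
prev_a: 0.01
prev_b: 0.01
uptake_a: 1.0
uptake_b: 1.0
alpha: 0.05
power: 0.80
target_test: wald
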