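# Demo analysis: synthetic city, 200 participants, full three-method comparison.
synth: true
synth_n: 200
synth_clusters: 15
seed: 7
trims: [25.0]
methods: [sausage, detailed_trimmed, detailed]
strata: pooled
alpha: 0.05
out_dir: bufcomp_out
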