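mode: synthetic
bank: memory_like
biomarkers: [amyloid, hippocampus]
strata: [full, CN, MCI, AD]
sampler: {chains: 3, iterations: 1000, warmup: 200}
seed: 1
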