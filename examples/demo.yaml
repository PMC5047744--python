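# Demo pipeline configuration: synthetic study with genomic input (n=4),
# a bromodomain pulldown (n=4) and a fusion-protein pulldown (n=2).
outdir: results/demo
seed: 42
mz_tolerance_da: 0.4
loq_fraction: 0.001
variability_mode: max_dev
comparisons:
  - [input, BRD4short]
  - [input, B4N]
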