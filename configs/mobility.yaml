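# Electrophoretic mobility curves, synthetic measurements and scenario fit.
experiment: mobility
seed: 7
outdir: results/mobility
mobility:
  scenario: outer
  noise_sd: 0.02
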