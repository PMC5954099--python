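# Probe distribution under non-crowded vs crowded grafting (quadrant shift).
experiment: distribution
seed: 7
outdir: results/distribution
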