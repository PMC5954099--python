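# Synthetic cytometry and antigen protection analysis (RhD, CD47).
experiment: camouflage
seed: 7
outdir: results/camouflage
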