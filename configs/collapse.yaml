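# Crowder titration: glycocalyx height/density collapse, dose-dependent
# Q1->Q4 shift and photobleach-normalized dextran concentration.
experiment: collapse
seed: 7
outdir: results/collapse
collapse:
  doses: [0.0, 57.5, 115.0, 230.0]
  compressions: [1.0, 0.85, 0.7, 0.55]
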