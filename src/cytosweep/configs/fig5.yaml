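# Cytoplasmic incompatibility (model iii): uninfected-origin invasion over
# (mu, t), one panel per CI strength h.  The h values are a configurable
# default spanning weak to moderate CI.  Each panel's mu
# range is clipped to the cells below the feasibility bound (1-sqrt(1-h))/2
# by the symbiont_absent marking.
schema: 1
model: iii
mode: sweep
params: {h: 0.01, t: 0.0, mu: 0.0}
origin: uninfected
h_list: [0.01, 0.05, 0.1, 0.25]
grid:
  axis1: {name: mu, lo: 0.0, hi: 0.07, n: 26}
  axis2: {name: t, lo: 0.0, hi: 0.02, n: 26}
output: fig5_sweep.csv
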