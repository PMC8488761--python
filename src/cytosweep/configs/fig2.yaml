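# Fixed-benefit symbiont (model i): uninfected-origin invasion phase diagram
# over (mu, t).  B = 0.1 is this package's documented default for the
# fixed symbiont benefit.
schema: 1
model: i
mode: sweep
params: {B: 0.1, t: 0.0, mu: 0.0}
origin: uninfected
grid:
  axis1: {name: mu, lo: 0.0, hi: 0.1, n: 51}
  axis2: {name: t, lo: 0.0, hi: 0.05, n: 51}
output: fig2_sweep.csv
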