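# Frequency-dependent benefit (model ii): uninfected-origin invasion phase
# diagram with carriage cost c = 0.01 and b = 0.1 (documented default).
schema: 1
model: ii
mode: sweep
params: {b: 0.1, c: 0.01, t: 0.0, mu: 0.0}
origin: uninfected
grid:
  axis1: {name: mu, lo: 0.0, hi: 0.09, n: 51}
  axis2: {name: t, lo: 0.0, hi: 0.05, n: 51}
output: fig3_sweep.csv
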