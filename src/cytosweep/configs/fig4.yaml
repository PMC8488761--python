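# Frequency-dependent benefit (model ii): uninfected-origin mitotype invades
# but coexists; mitotype variation partitions between infection classes.
schema: 1
model: ii
mode: trajectory
params: {b: 0.1, c: 0.05, mu: 0.02, t: 0.02}
origin: uninfected
epsilon: 1.0e-5
output: fig4_trajectory.csv
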