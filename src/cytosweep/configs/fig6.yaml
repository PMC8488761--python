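# Cytoplasmic incompatibility (model iii): infected-origin beneficial
# mitotype sweeps to fixation; symbiont stays at the upper equilibrium E3.
schema: 1
model: iii
mode: trajectory
params: {h: 0.25, mu: 0.05, t: 0.02}
origin: infected
epsilon: 1.0e-5
output: fig6_trajectory.csv
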