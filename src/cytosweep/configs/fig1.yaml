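# Fixed-benefit symbiont (model i): beneficial mitotype arising in an
# infected host sweeps to fixation; symbiont prevalence returns to baseline.
schema: 1
model: i
mode: trajectory
params: {B: 0.075, mu: 0.05, t: 0.02}
origin: infected
epsilon: 1.0e-5
output: fig1_trajectory.csv
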