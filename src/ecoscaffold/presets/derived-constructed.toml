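# Synthetic "derived" trait set: equal high growth rates, maximally
# asymmetric competition, stable interior fixed point of G at 0.5.
# Constructed analytically; not harvested from an evolutionary run.
scenario = "neutral_collapse"
seed = 0
initial_colour = 0.5

[lifecycle]
D = 1000
B = 15
T = 1.0
rho = 0.2
phi_hat = 0.5
M = 100
regime = "neutral"

[traits.red]
r = 25.0
a_intra = 0.0005333333333333334
a_inter = 0.0003333333333333333

[traits.blue]
r = 25.0
a_intra = 0.0002
a_inter = 0.0

[mutation]
traits = []
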