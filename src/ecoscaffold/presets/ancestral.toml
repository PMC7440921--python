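# Ancestral traits under the neutral regime (mutation off): ecology only.
scenario = "neutral_collapse"
seed = 0

[lifecycle]
D = 1000
B = 15
T = 1.0
rho = 0.2
phi_hat = 0.5
M = 100
regime = "neutral"

[traits.red]
r = 6.0
a_intra = 0.0005333333333333334
a_inter = 0.0001

[traits.blue]
r = 4.0
a_intra = 0.0002
a_inter = 0.0001

[mutation]
traits = []
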