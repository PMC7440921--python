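# Constrained evolution: only inter-colour competition mutates, r fixed at 25.
scenario = "constrained_ainter"
seed = 0

[lifecycle]
D = 1000
B = 15
T = 1.0
rho = 0.2
phi_hat = 0.5
M = 300
regime = "selective"

[traits.red]
r = 25.0
a_intra = 0.0005333333333333334
a_inter = 0.0001

[traits.blue]
r = 25.0
a_intra = 0.0002
a_inter = 0.0001

[mutation]
traits = ["a_inter"]
sigma = 0.05
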