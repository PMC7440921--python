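# Constrained evolution: only growth rates mutate, no competition.
scenario = "constrained_r"
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
r = 6.0
a_intra = 0.0
a_inter = 0.0

[traits.blue]
r = 5.0
a_intra = 0.0
a_inter = 0.0

[mutation]
traits = ["r"]
sigma = 0.05
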