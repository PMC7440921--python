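"""Reference parameter sets.

``ANCESTRAL_RED`` / ``ANCESTRAL_BLUE`` are the published ancestral particle
traits (growth rates 6 and 4; competition coefficients 0.8/K, 0.3/K and
0.15/K with K = 1500) used throughout the original selection experiments,
together with the standard scaffold (D = 1000 collectives, bottleneck
B = 15, growth duration T = 1, extinction fraction rho = 0.2, target colour
phi_hat = 0.5, M = 10000 generations).

``DERIVED_RED`` / ``DERIVED_BLUE`` is a constructed trait set realising the
geometry that long selective runs evolve towards: equal, high growth rates
(r = 25), the blue inter-colour coefficient at zero and the red inter-colour
coefficient at ``a0intra - a1intra``, which places the stable interior fixed
point of G exactly at phi* = 0.5 with a flat (canalised) slope. The evolved
values themselves are realisation-dependent and are not published; this set
is synthetic by construction.
"""

from __future__ import annotations

from .lifecycle import LifeCycleParams, MutationKernel
from .particles import ParticleType

K = 1500.0

ANCESTRAL_RED = ParticleType(colour="red", r=6.0, a_intra=0.8 / K, a_inter=0.15 / K)
ANCESTRAL_BLUE = ParticleType(colour="blue", r=4.0, a_intra=0.3 / K, a_inter=0.15 / K)

#: synthetic derived trait set (see module docstring); phi* = 0.5
DERIVED_RED = ParticleType(colour="red", r=25.0, a_intra=0.8 / K, a_inter=0.5 / K)
DERIVED_BLUE = ParticleType(colour="blue", r=25.0, a_intra=0.3 / K, a_inter=0.0)

#: scaffold of the reference selection experiment
STANDARD_PARAMS = LifeCycleParams(
    D=1000, B=15, T=1.0, rho=0.2, phi_hat=0.5, M=10000, regime="selective"
)

#: default mutation kernel: r and a_inter mutable, 5% relative Gaussian steps
DEFAULT_KERNEL = MutationKernel(traits=frozenset({"r", "a_inter"}), sigma=0.05)
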