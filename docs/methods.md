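# Methods

## The nested model

Two levels of demography are simulated explicitly.

**Particles.** Each collective holds up to four particle populations:
resident and mutant types of each colour (red, blue). A type carries four
heritable traits: colour *c*, maximum net growth rate *r* (> 0, per unit
time), and two competition coefficients *a*<sup>intra</sup>,
*a*<sup>inter</sup> (≥ 0, per particle). Birth of type *i* occurs at rate
*r<sub>i</sub>N<sub>i</sub>*; death at rate
*N<sub>i</sub> r<sub>i</sub>* Σ<sub>j</sub> *a<sub>j</sub>N<sub>j</sub>*,
with *a<sub>j</sub>* the intra- or inter-colour coefficient of *j* according
to whether *j* shares the colour of *i*. The competition sum includes the
focal particle itself: this makes the expected dynamics equal the
Lotka–Volterra field d*x<sub>i</sub>*/dt = *r<sub>i</sub>x<sub>i</sub>*(1 −
Σ*a·x*) exactly, and the O(1/N) self-term is far below demographic noise.
Only competitive (non-negative) coefficients are supported; exploitative or
mutualistic interactions are out of scope.

**Collectives.** D collectives follow discrete, non-overlapping generations:
grow for duration T; rank adults by |ϕ − ϕ̂| (selective regime) or uniformly
at random (neutral regime); extinguish the worst round(ρD) (ties broken
uniformly at random; demographically empty collectives rank as infinitely
bad); replace each extinguished slot with offspring of an extant survivor
drawn uniformly with replacement; every survivor is replaced by its own
offspring. Offspring receive B founder particles sampled without replacement
(multivariate hypergeometric) from the parent; a parent with fewer than B
particles transmits all of them. Lineages never mix. If every lineage is
extinct the run terminates with a lineage-extinction report.

**Mutation.** Following the adaptive-dynamics bookkeeping of residents and
mutants, one mutant is introduced whenever one of the two populations of a
colour is absent at founding while the other is present: the survivor is
(re)labelled resident and a single mutant particle is added whose traits
equal the resident's with one mutable trait (chosen uniformly from the
kernel's set, by default {r, a<sup>inter</sup>}) perturbed by a Gaussian
step and truncated at zero. Introduction happens once per collective
generation, at founding (after dilution, before growth), which keeps the
within-growth dynamics closed; introduction at the instant of within-growth
extinction is a conceivable alternative that is not implemented. The step
standard deviation is *relative* to the current trait value (default σ =
5%), so the same kernel acts sensibly on r (order 1–10) and on a (order
10⁻⁴); a trait exactly at zero therefore no longer mutates, which matches
the evolutionary endpoints studied here. The exact kernel used in the
original experiments is not published; σ is exposed in every configuration.

## Exact stochastic simulation

The within-collective process is sampled exactly by the direct SSA: an
exponential waiting time at the total event rate, then a categorical event
choice. The production kernel (numba) maintains four aggregates — per-colour
competition pressure and per-colour total birth rate — updated in O(1) per
event and recomputed from scratch every 2²⁰ events, so accumulated
floating-point drift stays below 10⁻¹⁰ of the rates; a pure-Python reference
implementation recomputes all rates every event and is tested against the
kernel. When every competition coefficient of the populations present is
zero the process is pure birth (Yule), and the adult counts are drawn from
the exact marginal N(T) ~ N₀ + NegBin(N₀, e^(−rT)) instead of event by
event; this is an exact sampler of the same distribution, not an
approximation (no tau-leaping anywhere), and is what makes the
growth-rates-only evolution experiments tractable when e^(rT) is large.
Populations above 10¹⁵ particles abort with a feasibility error rather than
overflow.

**Random streams.** A master seed splits into per-stage substreams via
`SeedSequence((master, stage, generation, collective))` with stage 0 =
initialisation, 1 = growth, 2 = extinction choice, 3 = parent assignment,
4 = founding + mutation. Runs are replayable bit-identically, collective by
collective, and adding collectives leaves existing growth streams unchanged.

## The growth function

G(ϕ) integrates the competitive Lotka–Volterra ODE from real-valued initial
masses (Bϕ, B(1−ϕ)) for time T (RK45, rtol 10⁻¹⁰, atol 10⁻¹²) and returns
the adult red fraction. Real-valued founders are deliberate: G is the
vanishing-noise limit of the stochastic layer, whose replicate mean matches
G within Monte-Carlo error (tested). Grid evaluations integrate all initial
conditions as one decoupled ensemble system (rtol 10⁻⁸), which keeps
fixed-point scans and phase diagrams fast.

Fixed points of G on [0, 1] are located by sign-change bracketing on a
uniform grid (default resolution 10⁻³) refined by Brent's method to 10⁻⁸;
ϕ = 0 and ϕ = 1 are always fixed points, with stability read from the
displacement G − id at the adjacent grid points. A root is stable when the
displacement crosses from + to −. Shapes are classified as: no interior
root with ϕ = 1 stable (red fixation) or ϕ = 0 stable (blue fixation); one
stable interior root; one unstable interior root (bistable boundaries); the
degenerate identity map (|G − id| < 10⁻⁷ everywhere, e.g. a = 0 with
r0 = r1); anything else is reported verbatim as its root list. Roots closer
to a boundary than the grid resolution may be missed; the default grid makes
that region 10⁻³ wide.

The staircase iteration ϕ ← G(ϕ) models noise-free serial passage. Its
fixation stop rule, B·min(ϕ, 1−ϕ) < 0.5, declares the majority colour fixed
once the expected minority founder count at the next bottleneck drops below
half a particle — the natural discretisation threshold for an integer
bottleneck of size B. The slope dG/dϕ uses a central difference with step
10⁻⁴ (clipped inside (0,1)), two orders above the integration error. The
(B, T) phase diagram runs the fixed-point classifier per grid cell
(default cell grid 401 points) and reports, per bottleneck size, the
smallest duration with a stable interior point; this numerical contour is
the contract — no analytic boundary is derived.

## Reference parameter sets

The ancestral traits and scaffold are the published reference conditions:
red (r = 6, a<sup>intra</sup> = 0.8/1500, a<sup>inter</sup> = 0.15/1500),
blue (r = 4, a<sup>intra</sup> = 0.3/1500, a<sup>inter</sup> = 0.15/1500),
D = 1000, B = 15, T = 1, ρ = 0.2, ϕ̂ = 0.5, M = 10000. These traits satisfy
the coexistence signs with ϕ\* = 0.1875 and carrying capacities K₀ = 1875,
K₁ = 5000.

The "derived" trait set bundled as `derived-constructed.toml` is synthetic:
equal high growth rates (r = 25), the inter-colour coefficient acting on the
lower-carrying-capacity type at zero (a01 = 0) and the other at
a00 − a11 = 0.5/1500, which places the stable interior fixed point of G
exactly at 0.5 with near-maximal flatness. It realises analytically the
geometry that long selective runs evolve towards; the actually evolved
values are realisation-dependent and unpublished.

For the growth-rates-only constrained experiment the initial rates are not
published either. The package default is (6, 5): with no competition the
per-generation colour bias is e^((r0−r1)T), and a unit gap is the largest
asymmetry of the ancestral scale that the desk-scale scaffold (D = 100)
sustains long enough for alignment to be observed; with the ancestral gap of
2 the blue type is lost within about ten generations in every realisation.
The competition-only experiment fixes r0 = r1 = 25 with ancestral
intra-colour coefficients.

## Desk scaling and what the tests show

The published experiments run at D = 1000 for 10⁴ generations. The test
suite replays them at reduced scale, chosen so the whole suite stays within
minutes on one CPU: neutral collapse at D = 200 (collapse at generation
9–12 across seeds, against the printed "fewer than ten" at full scale — a
max-statistic over D lineages plus down-scaling noise); the selective
experiment at D = 100 for 500 generations, which at 5% mutation steps
already traverses the stochastic-corrector phase and the onset of
developmental correction; constrained evolution at D = 100 for 300
generations. At D = 100 roughly half of all realisations lose the blue type
outright (collective-lineage extinction) — a real failure mode of small
collective populations, absent at full scale — so stochastic demonstrations
run under fixed seeds and say so.

The synthetic-data layer *is* the model: no external data exist, and every
test input is generated by the simulator or constructed analytically. What
passing tests do not show: behaviour at full scale (D = 1000, M = 10⁴) is
checked only through the deterministic layer and scaled proxies; mutation
kernels other than relative-Gaussian are untested; and the model itself
idealises real communities (two types, no migration or mixing between
collectives, no spatial structure, competition-only interactions,
equally-timed reproduction).

## Numerical choices and edge cases

- Extinction count round(ρD) uses banker's rounding via `numpy.rint`;
  configurations with ρ > 0 but round(ρD) = 0 are rejected.
- Colour of an empty collective is undefined (NaN in records); empty
  survivors in the neutral regime persist as empty lineages and are excluded
  from the replacement-parent pool.
- Founding at generation 0 sets the red count to round(pB), p ~ U(0,1), so
  every collective holds exactly B particles while ratios stay uniform.
- Offspring founding for parents above 10⁸ particles switches from numpy's
  multivariate hypergeometric sampler to exact sequential weighted draws
  without replacement (same distribution, no size limit).
- G is evaluated with x = 0 preserved exactly, so G(0) = 0 and G(1) = 1
  hold to machine precision; tiny negative integrator excursions are clipped
  to zero.
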