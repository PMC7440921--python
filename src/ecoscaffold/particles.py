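"""Stochastic birth-death dynamics of particles within a single collective.

A collective holds up to four particle populations (resident and mutant of
each of the two colours). Particles of type *i* reproduce at a constant
per-capita rate ``r_i`` and die from density-dependent competition: each
particle of type *j* adds ``r_i * a_j`` to the death rate of every *i*
particle, where ``a_j`` is ``a_j^intra`` if *i* and *j* share a colour and
``a_j^inter`` otherwise. In the large-population limit this is the
competitive Lotka-Volterra system handled by :mod:`ecoscaffold.gfunction`.

The module exposes an exact stochastic simulation algorithm (direct method)
in three flavours: a pure-Python reference implementation
(:func:`gillespie_step` / :func:`simulate_growth`), a numba-compiled kernel
(:mod:`ecoscaffold._engine`) used by the life-cycle layer, and an exact
negative-binomial sampler for the non-interacting (pure birth, Yule) case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

RED = 0
BLUE = 1
COLOUR_NAMES = ("red", "blue")

# slot layout used by the array-based life-cycle representation
RED_RES, RED_MUT, BLUE_RES, BLUE_MUT = 0, 1, 2, 3
SLOT_COLOUR = np.array([RED, RED, BLUE, BLUE], dtype=np.int64)
SLOT_ROLE = ("resident", "mutant", "resident", "mutant")
# trait columns in the (4, 3) per-collective trait array
TR_R, TR_A_INTRA, TR_A_INTER = 0, 1, 2

#: populations larger than this abort the run instead of overflowing int64
MAX_POPULATION = 10 ** 15


class InvalidStateError(ValueError):
    """A collective state violates its invariants (e.g. negative count)."""


class UndefinedColourError(ValueError):
    """Colour requested for an empty (extinct) collective."""


class FeasibilityError(RuntimeError):
    """The simulated population exceeds :data:`MAX_POPULATION`."""


@dataclass(frozen=True)
class ParticleType:
    """One heritable particle type.

    Parameters
    ----------
    colour:
        ``"red"`` or ``"blue"``. Immutable under mutation.
    r:
        Maximum net growth rate (per unit time), > 0.
    a_intra:
        Per-capita competitive effect on same-colour particles (per
        particle), >= 0. The monoculture carrying capacity is ``1/a_intra``.
    a_inter:
        Per-capita competitive effect on different-colour particles (per
        particle), >= 0.
    role:
        ``"resident"`` or ``"mutant"`` (adaptive-dynamics bookkeeping).
    """

    colour: str
    r: float
    a_intra: float
    a_inter: float
    role: str = "resident"

    def __post_init__(self) -> None:
        if self.colour not in COLOUR_NAMES:
            raise InvalidStateError(f"colour must be 'red' or 'blue', got {self.colour!r}")
        if self.role not in ("resident", "mutant"):
            raise InvalidStateError(f"role must be 'resident' or 'mutant', got {self.role!r}")
        if not self.r > 0:
            raise InvalidStateError(f"r must be > 0, got {self.r}")
        if self.a_intra < 0 or self.a_inter < 0:
            raise InvalidStateError("competition coefficients must be >= 0")

    @property
    def colour_index(self) -> int:
        return COLOUR_NAMES.index(self.colour)

    def traits_array(self) -> np.ndarray:
        return np.array([self.r, self.a_intra, self.a_inter], dtype=float)


@dataclass
class CollectiveState:
    """Integer particle counts of up to four populations in one collective.

    ``populations`` is a list of ``(ParticleType, count)`` pairs with at most
    one resident and one mutant per colour. ``clock`` is the elapsed
    within-generation time in ``[0, T]``.
    """

    populations: list[tuple[ParticleType, int]] = field(default_factory=list)
    clock: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for ptype, count in self.populations:
            if not isinstance(count, (int, np.integer)):
                raise InvalidStateError(f"counts must be integers, got {count!r}")
            if count < 0:
                raise InvalidStateError(f"negative count {count} for {ptype}")
            key = (ptype.colour, ptype.role)
            if key in seen:
                raise InvalidStateError(f"duplicate population slot {key}")
            seen.add(key)
        if self.clock < 0:
            raise InvalidStateError("clock must be >= 0")

    @property
    def total(self) -> int:
        return int(sum(count for _, count in self.populations))

    def colour_total(self, colour: str) -> int:
        return int(sum(c for p, c in self.populations if p.colour == colour))


def adult_colour(state: CollectiveState) -> float:
    """Fraction of red particles, the collective phenotype phi in [0, 1].

    Raises :class:`UndefinedColourError` for an empty collective (the
    life-cycle layer flags such collectives instead of asking).
    """
    total = state.total
    if total == 0:
        raise UndefinedColourError("colour is undefined for an empty collective")
    return state.colour_total("red") / total


def event_rates(state: CollectiveState) -> tuple[np.ndarray, np.ndarray]:
    """Per-population birth and death rates of the direct-method SSA.

    For population *i* with count ``N_i``: birth rate ``r_i * N_i`` and death
    rate ``N_i * r_i * sum_j a_j * N_j`` with ``a_j = a_j^intra`` when *j*
    shares colour *i* and ``a_j^inter`` otherwise (the sum includes *i*
    itself, matching the Lotka-Volterra limit exactly).
    """
    state.validate()
    n = len(state.populations)
    birth = np.zeros(n)
    death = np.zeros(n)
    # competition pressure felt by each colour
    pressure = {RED: 0.0, BLUE: 0.0}
    for ptype, count in state.populations:
        ci = ptype.colour_index
        pressure[ci] += ptype.a_intra * count
        pressure[1 - ci] += ptype.a_inter * count
    for i, (ptype, count) in enumerate(state.populations):
        birth[i] = ptype.r * count
        death[i] = count * ptype.r * pressure[ptype.colour_index]
    return birth, death


def gillespie_step(
    state: CollectiveState, rng: np.random.Generator
) -> CollectiveState | None:
    """One exact SSA event (direct method); ``None`` when no event can occur.

    The clock advances by an exponential waiting time with the total event
    rate and exactly one population count changes by +/-1.
    """
    birth, death = event_rates(state)
    total = float(birth.sum() + death.sum())
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    rates = np.concatenate([birth, death])
    idx = int(np.searchsorted(np.cumsum(rates), u, side="right"))
    idx = min(idx, len(rates) - 1)
    pop_idx, is_death = idx % len(birth), idx >= len(birth)
    new_pops = list(state.populations)
    ptype, count = new_pops[pop_idx]
    new_pops[pop_idx] = (ptype, count - 1 if is_death else count + 1)
    return CollectiveState(populations=new_pops, clock=state.clock + dt)


def _yule_adult_counts(
    counts: np.ndarray, rates: np.ndarray, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact adult counts for the pure-birth (Yule) process.

    With no competition each lineage grows independently and the population
    at time T founded by N0 particles is N0 + NegativeBinomial(N0, e^{-rT}),
    the exact marginal of the Yule process. Sampling this closed form is
    distribution-identical to running the SSA event by event.
    """
    out = counts.astype(np.int64).copy()
    for j in range(len(out)):
        n0 = int(out[j])
        if n0 == 0 or rates[j] <= 0 or T <= 0:
            continue
        p = math.exp(-rates[j] * T)
        if n0 / p > MAX_POPULATION:
            raise FeasibilityError(
                f"expected population {n0 / p:.3g} exceeds {MAX_POPULATION:.0e}"
            )
        out[j] = n0 + rng.negative_binomial(n0, p)
    return out


def _is_pure_birth(state: CollectiveState) -> bool:
    return all(
        p.a_intra == 0.0 and p.a_inter == 0.0 for p, c in state.populations if c > 0
    )


def simulate_growth(
    newborn: CollectiveState,
    T: float,
    rng: np.random.Generator,
    method: str = "auto",
) -> CollectiveState:
    """Grow a newborn collective for a duration ``T``; return the adult.

    Repeats exact SSA events until the clock reaches ``T`` or no further
    event is possible; the clock is capped at ``T``. ``method`` selects the
    implementation: ``"reference"`` (pure-Python direct method), ``"ssa"``
    (numba direct-method kernel), ``"yule"`` (exact negative-binomial
    sampler, valid only without competition) or ``"auto"`` (yule when all
    competition coefficients of the populations present are zero, else the
    numba kernel). All are exact samplers of the same process.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if T == 0 or newborn.total == 0:
        return replace(newborn, clock=min(newborn.clock, T))
    if method == "auto":
        method = "yule" if _is_pure_birth(newborn) else "ssa"

    if method == "reference":
        state = newborn
        while state.clock < T:
            nxt = gillespie_step(state, rng)
            if nxt is None:
                break
            if nxt.clock > T:  # event would land past the horizon
                state = replace(state, clock=T)
                break
            state = nxt
        return replace(state, clock=min(max(state.clock, 0.0), T))

    counts, types = _state_arrays(newborn)
    if method == "yule":
        if not _is_pure_birth(newborn):
            raise ValueError("yule method requires all competition coefficients 0")
        rates = np.array([p.r for p in types])
        counts = _yule_adult_counts(counts, rates, T, rng)
    elif method == "ssa":
        from ._engine import ssa_growth

        traits = np.stack([p.traits_array() for p in types])
        colour = np.array([p.colour_index for p in types], dtype=np.int64)
        seed = int(rng.integers(0, 2 ** 32))
        ssa_growth(counts, colour, traits[:, TR_R].copy(),
                   traits[:, TR_A_INTRA].copy(), traits[:, TR_A_INTER].copy(),
                   float(T), seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    pops = [(p, int(c)) for p, c in zip(types, counts)]
    return CollectiveState(populations=pops, clock=T)


def _state_arrays(state: CollectiveState) -> tuple[np.ndarray, list[ParticleType]]:
    counts = np.array([c for _, c in state.populations], dtype=np.int64)
    types = [p for p, _ in state.populations]
    return counts, types
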