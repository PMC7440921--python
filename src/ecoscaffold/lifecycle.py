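"""Collective-level death-birth scaffold.

Collectives follow discrete, non-overlapping generations: ``D`` collectives
are founded with ``B`` particles each, grown for a duration ``T`` (exact
stochastic birth-death of the particles), and a fixed fraction ``rho`` of
the adults is extinguished -- uniformly at random (*neutral* regime) or
ranked by distance of the adult colour from a target ``phi_hat``
(*selective* regime). Extinguished collectives are replaced by offspring of
uniformly sampled extant survivors; every survivor is replaced by its own
offspring; lineages never mix. Offspring are founded by sampling ``B``
particles without replacement (multivariate hypergeometric) from the parent.

Mutation uses the adaptive-dynamics bookkeeping of resident and mutant
types: whenever one of the two populations of a colour is absent at founding
while the other is present, the survivor is (re)labelled resident and a
single mutant particle is introduced whose traits equal the resident's with
one mutable trait perturbed.

Randomness is replayable collective-by-collective: the master seed splits
into per-stage substreams via ``np.random.SeedSequence((master, stage,
generation, collective))`` (stage 0 = initialisation, 1 = growth,
2 = extinction choice, 3 = parent assignment, 4 = founding + mutation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .particles import (
    BLUE_MUT,
    BLUE_RES,
    COLOUR_NAMES,
    MAX_POPULATION,
    RED_MUT,
    RED_RES,
    SLOT_COLOUR,
    TR_A_INTER,
    TR_A_INTRA,
    TR_R,
    FeasibilityError,
    ParticleType,
    _yule_adult_counts,
)

_RES_SLOT = {"red": RED_RES, "blue": BLUE_RES}
_MUT_SLOT = {"red": RED_MUT, "blue": BLUE_MUT}
_TRAIT_COL = {"r": TR_R, "a_intra": TR_A_INTRA, "a_inter": TR_A_INTER}


class LineageExtinctionError(RuntimeError):
    """Every collective is extinct; the run terminates with a report."""


class CannotReproduceError(ValueError):
    """An empty collective was asked to produce offspring."""


@dataclass(frozen=True)
class LifeCycleParams:
    """The collective-level scaffold.

    D: number of collectives (constant across generations).
    B: bottleneck size, the number of founding particles per offspring.
    T: particle growth duration per collective generation.
    rho: fraction of collectives extinguished per generation, in [0, 1).
    phi_hat: target colour in (0, 1) (selective regime only).
    M: number of collective generations.
    regime: "neutral" (random extinction) or "selective" (rank by
        |phi - phi_hat|).
    """

    D: int
    B: int
    T: float
    rho: float = 0.0
    phi_hat: float = 0.5
    M: int = 1
    regime: str = "neutral"

    def __post_init__(self) -> None:
        if self.D < 1 or self.B < 1:
            raise ValueError("D and B must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.phi_hat < 1.0:
            raise ValueError("phi_hat must be in (0, 1)")
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.regime not in ("neutral", "selective"):
            raise ValueError(f"regime must be 'neutral' or 'selective', got {self.regime!r}")
        if self.rho > 0 and self.n_extinct < 1:
            raise ValueError("round(rho * D) must be >= 1 when rho > 0")

    @property
    def n_extinct(self) -> int:
        return int(np.rint(self.rho * self.D))


@dataclass(frozen=True)
class MutationKernel:
    """Mutation scheme applied at mutant introduction.

    ``traits`` is the subset of {"r", "a_inter"} that may mutate (an empty
    set disables mutation entirely). The perturbation adds a Gaussian step
    with standard deviation ``sigma`` *relative* to the current trait value
    (scale-free across traits of very different magnitude) and truncates the
    result at zero. One trait, chosen uniformly from ``traits``, mutates per
    introduction.
    """

    traits: frozenset = frozenset({"r", "a_inter"})
    sigma: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", frozenset(self.traits))
        bad = self.traits - {"r", "a_inter"}
        if bad:
            raise ValueError(f"mutable traits must be within {{'r', 'a_inter'}}, got {bad}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def enabled(self) -> bool:
        return bool(self.traits)

    def perturb(self, trait_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Return a mutated copy of a (r, a_intra, a_inter) trait row."""
        out = trait_row.copy()
        choices = sorted(self.traits)
        name = choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices[0]
        col = _TRAIT_COL[name]
        value = out[col]
        out[col] = max(0.0, value + rng.normal(0.0, self.sigma * abs(value)))
        return out


DISABLED_KERNEL = MutationKernel(traits=frozenset())


@dataclass
class PopulationState:
    """Array-based state of the whole population of collectives.

    ``counts[i, s]`` is the particle count of slot ``s`` (red resident, red
    mutant, blue resident, blue mutant) in collective ``i``;
    ``traits[i, s]`` holds its (r, a_intra, a_inter).
    """

    counts: np.ndarray  # (D, 4) int64
    traits: np.ndarray  # (D, 4, 3) float64
    generation: int = 0

    @property
    def D(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def red_totals(self) -> np.ndarray:
        return self.counts[:, [RED_RES, RED_MUT]].sum(axis=1)

    def colours(self) -> np.ndarray:
        """Adult colour per collective; NaN for empty collectives."""
        tot = self.totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = self.red_totals() / tot
        phi[tot == 0] = np.nan
        return phi

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.traits.copy(), self.generation)


@dataclass
class GenerationRecord:
    """Per-generation bookkeeping of one collective generation."""

    generation: int
    colours: np.ndarray  # adult colours, NaN = extinct
    mean_colour: float
    sd_colour: float
    q25_colour: float
    median_colour: float
    q75_colour: float
    n_extant: int
    n_dichromatic: int
    n_red_mono: int
    n_blue_mono: int
    n_empty: int
    n_mutants: int
    extinct_indices: np.ndarray
    resident_trait_means: dict

    def summary_row(self) -> dict:
        row = {
            "generation": self.generation,
            "mean_colour": self.mean_colour,
            "sd_colour": self.sd_colour,
            "q25_colour": self.q25_colour,
            "median_colour": self.median_colour,
            "q75_colour": self.q75_colour,
            "n_extant": self.n_extant,
            "n_dichromatic": self.n_dichromatic,
            "n_red_mono": self.n_red_mono,
            "n_blue_mono": self.n_blue_mono,
            "n_empty": self.n_empty,
            "n_mutants": self.n_mutants,
            "n_extinguished": len(self.extinct_indices),
        }
        row.update(self.resident_trait_means)
        return row


@dataclass
class Trajectory:
    """Outcome of ``run_evolution``: one record per collective generation."""

    records: list[GenerationRecord]
    final: PopulationState
    params: LifeCycleParams
    kernel: MutationKernel
    seed: int
    status: str = "completed"

    @property
    def n_generations(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.records])

    def colours_matrix(self) -> np.ndarray:
        """(n_generations, D) matrix of adult colours (NaN = extinct)."""
        if not self.records:
            return np.empty((0, self.final.D))
        return np.stack([r.colours for r in self.records])

    def first_all_monochromatic(self) -> int | None:
        """First generation at which no collective contains both colours."""
        for rec in self.records:
            if rec.n_dichromatic == 0:
                return rec.generation
        return None


def _seed_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + key))


def founder_fractions(D: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform founding red fractions p ~ U(0, 1), one per collective."""
    return rng.random(D)


def init_population(
    D: int,
    B: int,
    red: ParticleType,
    blue: ParticleType,
    rng: np.random.Generator,
) -> PopulationState:
    """Found ``D`` collectives of ``B`` particles with uniform colour ratios.

    The red founder count is ``round(p * B)`` with ``p`` drawn uniformly per
    collective; mutant slots start empty (first mutants enter via the
    extinction rule at the next founding).
    """
    if D < 1 or B < 1:
        raise ValueError("D and B must be >= 1")
    p = founder_fractions(D, rng)
    red_counts = np.rint(p * B).astype(np.int64)
    counts = np.zeros((D, 4), dtype=np.int64)
    counts[:, RED_RES] = red_counts
    counts[:, BLUE_RES] = B - red_counts
    traits = np.zeros((D, 4, 3))
    traits[:, RED_RES] = traits[:, RED_MUT] = red.traits_array()
    traits[:, BLUE_RES] = traits[:, BLUE_MUT] = blue.traits_array()
    return PopulationState(counts=counts, traits=traits, generation=0)


def population_from_colours(
    colours: Sequence[float],
    B: int,
    red: ParticleType,
    blue: ParticleType,
) -> PopulationState:
    """Found collectives with prescribed newborn colours (round(phi*B) red)."""
    phis = np.asarray(colours, dtype=float)
    if np.any((phis < 0) | (phis > 1)):
        raise ValueError("colours must lie in [0, 1]")
    D = len(phis)
    counts = np.zeros((D, 4), dtype=np.int64)
    counts[:, RED_RES] = np.rint(phis * B).astype(np.int64)
    counts[:, BLUE_RES] = B - counts[:, RED_RES]
    traits = np.zeros((D, 4, 3))
    traits[:, RED_RES] = traits[:, RED_MUT] = red.traits_array()
    traits[:, BLUE_RES] = traits[:, BLUE_MUT] = blue.traits_array()
    return PopulationState(counts=counts, traits=traits, generation=0)


def select_extinctions(
    colours: np.ndarray,
    params: LifeCycleParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the ``round(rho * D)`` collectives marked for extinction.

    Selective regime: the collectives whose adult colour departs most from
    ``phi_hat`` (empty collectives rank as infinitely bad; ties broken
    uniformly at random). Neutral regime: a uniform random subset.
    """
    D = len(colours)
    n_ext = params.n_extinct
    if n_ext == 0:
        return np.empty(0, dtype=np.int64)
    if params.regime == "neutral":
        return rng.choice(D, size=n_ext, replace=False).astype(np.int64)
    dist = np.abs(np.asarray(colours, dtype=float) - params.phi_hat)
    dist[np.isnan(dist)] = np.inf
    order = np.lexsort((rng.random(D), -dist))
    return np.sort(order[:n_ext]).astype(np.int64)


def assign_parents(
    extinct: np.ndarray,
    survivors: np.ndarray,
    D: int,
    rng: np.random.Generator,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Parent index per collective slot.

    Survivors map to themselves; each extinct slot gets a parent drawn
    uniformly (with replacement) from the extant survivors. ``eligible``
    restricts the replacement pool (defaults to all survivors).
    """
    pool = np.asarray(survivors if eligible is None else eligible, dtype=np.int64)
    if pool.size == 0:
        raise LineageExtinctionError("no extant collective can reproduce")
    parents = np.arange(D, dtype=np.int64)
    extinct = np.asarray(extinct, dtype=np.int64)
    if extinct.size:
        parents[extinct] = rng.choice(pool, size=extinct.size, replace=True)
    return parents


def found_offspring(
    parent_counts: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``B`` founding particles without replacement from a parent.

    Multivariate hypergeometric over the parent's four population counts; a
    parent with fewer than ``B`` particles transmits all of them.
    """
    parent_counts = np.asarray(parent_counts, dtype=np.int64)
    total = int(parent_counts.sum())
    if total == 0:
        raise CannotReproduceError("parent collective is empty")
    if total <= B:
        return parent_counts.copy()
    if total <= 10 ** 8:
        return rng.multivariate_hypergeometric(parent_counts, B).astype(np.int64)
    # huge parents: sequential weighted draws without replacement (exact)
    remaining = parent_counts.copy()
    out = np.zeros_like(remaining)
    left = total
    for _ in range(B):
        u = int(rng.integers(left))
        acc = 0
        for j in range(len(remaining)):
            acc += int(remaining[j])
            if u < acc:
                out[j] += 1
                remaining[j] -= 1
                left -= 1
                break
    return out


def introduce_mutants(
    counts: np.ndarray,
    traits: np.ndarray,
    kernel: MutationKernel,
    rng: np.random.Generator,
) -> int:
    """Apply the mutation-on-extinction rule to one newborn (in place).

    For each colour present whose resident or mutant slot is empty while the
    other slot is occupied: the surviving type is (re)labelled resident and
    one mutant particle with perturbed traits is added. Colours absent from
    the collective are never re-seeded. Returns the number of mutants added.
    """
    if not kernel.enabled:
        return 0
    n_added = 0
    for colour in COLOUR_NAMES:
        res, mut = _RES_SLOT[colour], _MUT_SLOT[colour]
        if counts[res] == 0 and counts[mut] == 0:
            continue  # colour absent: never re-seeded
        if counts[res] > 0 and counts[mut] > 0:
            continue  # both types present
        if counts[res] == 0:  # promote the surviving mutant to resident
            counts[res] = counts[mut]
            traits[res] = traits[mut]
            counts[mut] = 0
        traits[mut] = kernel.perturb(traits[res], rng)
        counts[mut] = 1
        n_added += 1
    return n_added


def _grow_population(
    pop: PopulationState, T: float, master_seed: int
) -> PopulationState:
    """Grow every collective for duration T (exact SSA / Yule per collective)."""
    from ._engine import ssa_growth

    adult = pop.copy()
    if T <= 0:
        return adult
    g = pop.generation
    counts = adult.counts
    traits = adult.traits
    for i in range(pop.D):
        row = counts[i]
        if row.sum() == 0:
            continue
        present = row > 0
        tr = traits[i]
        ss = np.random.SeedSequence((int(master_seed), 1, g, i))
        if not np.any(tr[present][:, [TR_A_INTRA, TR_A_INTER]]):
            rng = np.random.default_rng(ss)
            counts[i] = _yule_adult_counts(row, tr[:, TR_R], T, rng)
        else:
            seed = int(ss.generate_state(1)[0])
            ssa_growth(row, SLOT_COLOUR, tr[:, TR_R].copy(),
                       tr[:, TR_A_INTRA].copy(), tr[:, TR_A_INTER].copy(),
                       float(T), seed)
            if row.sum() > MAX_POPULATION:
                raise FeasibilityError("population exceeded MAX_POPULATION")
    return adult


def _resident_trait_means(pop: PopulationState) -> dict:
    out = {}
    for colour in COLOUR_NAMES:
        res = _RES_SLOT[colour]
        present = pop.counts[:, res] > 0
        for name, col in _TRAIT_COL.items():
            key = f"{name}_{colour}"
            out[key] = float(pop.traits[present, res, col].mean()) if present.any() else np.nan
    return out


def _colour_stats(colours: np.ndarray) -> dict:
    extant = colours[~np.isnan(colours)]
    if extant.size == 0:
        return dict(mean=np.nan, sd=np.nan, q25=np.nan, med=np.nan, q75=np.nan)
    return dict(
        mean=float(extant.mean()),
        sd=float(extant.std(ddof=0)),
        q25=float(np.quantile(extant, 0.25)),
        med=float(np.quantile(extant, 0.5)),
        q75=float(np.quantile(extant, 0.75)),
    )


def run_generation(
    pop: PopulationState,
    params: LifeCycleParams,
    kernel: MutationKernel,
    master_seed: int,
) -> tuple[PopulationState, GenerationRecord]:
    """One full collective generation: grow, select, reproduce, mutate."""
    g = pop.generation
    D = params.D
    if pop.D != D:
        raise ValueError("population size does not match params.D")

    adult = _grow_population(pop, params.T, master_seed)
    colours = adult.colours()
    totals = adult.totals()
    red_tot = adult.red_totals()

    extinct = select_extinctions(colours, params, _seed_rng(master_seed, 2, g))
    survivors = np.setdiff1d(np.arange(D), extinct)
    extant_survivors = survivors[totals[survivors] > 0]
    if extant_survivors.size == 0:
        raise LineageExtinctionError(
            f"all collective lineages extinct at generation {g}"
        )
    parents = assign_parents(
        extinct, survivors, D, _seed_rng(master_seed, 3, g), eligible=extant_survivors
    )

    new_counts = np.zeros_like(adult.counts)
    new_traits = adult.traits.copy()
    n_mutants = 0
    for i in range(D):
        p = int(parents[i])
        rng_i = _seed_rng(master_seed, 4, g, i)
        new_traits[i] = adult.traits[p]
        if totals[p] == 0:
            continue  # empty survivor lineage stays empty
        new_counts[i] = found_offspring(adult.counts[p], params.B, rng_i)
        n_mutants += introduce_mutants(new_counts[i], new_traits[i], kernel, rng_i)

    stats = _colour_stats(colours)
    blue_tot = totals - red_tot
    record = GenerationRecord(
        generation=g + 1,
        colours=colours,
        mean_colour=stats["mean"],
        sd_colour=stats["sd"],
        q25_colour=stats["q25"],
        median_colour=stats["med"],
        q75_colour=stats["q75"],
        n_extant=int((totals > 0).sum()),
        n_dichromatic=int(((red_tot > 0) & (blue_tot > 0)).sum()),
        n_red_mono=int(((red_tot > 0) & (blue_tot == 0)).sum()),
        n_blue_mono=int(((red_tot == 0) & (blue_tot > 0)).sum()),
        n_empty=int((totals == 0).sum()),
        n_mutants=n_mutants,
        extinct_indices=extinct,
        resident_trait_means=_resident_trait_means(adult),
    )
    new_pop = PopulationState(new_counts, new_traits, generation=g + 1)
    return new_pop, record


def run_evolution(
    params: LifeCycleParams,
    red: ParticleType,
    blue: ParticleType,
    seed: int,
    kernel: MutationKernel = DISABLED_KERNEL,
    initial: PopulationState | None = None,
    stop_when_monochromatic: bool = False,
) -> Trajectory:
    """Iterate ``params.M`` collective generations from a fresh population.

    ``initial`` overrides the uniformly-coloured founding population.
    ``stop_when_monochromatic`` ends the run early once no collective
    contains both colours (useful for neutral-collapse experiments; the
    triggering generation is still recorded).
    """
    if initial is None:
        pop = init_population(params.D, params.B, red, blue, _seed_rng(seed, 0))
    else:
        pop = initial.copy()
        if pop.D != params.D:
            raise ValueError("initial population size does not match params.D")
    records: list[GenerationRecord] = []
    status = "completed"
    for _ in range(params.M):
        try:
            pop, rec = run_generation(pop, params, kernel, seed)
        except LineageExtinctionError:
            status = "lineage_extinction"
            break
        records.append(rec)
        if stop_when_monochromatic and rec.n_dichromatic == 0:
            status = "monochromatic"
            break
    return Trajectory(
        records=records, final=pop, params=params, kernel=kernel,
        seed=int(seed), status=status,
    )
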