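"""Scenario runners recreating the in-silico selection experiments.

Each scenario wraps :func:`ecoscaffold.lifecycle.run_evolution` (or the
particle layer directly) with the configuration of one published experiment,
exposes ``scale_D`` / ``scale_M`` multipliers so the same scenario runs at
desk scale, and is bit-identically replayable under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import defaults
from .gfunction import GrowthFunctionSpec, TraitVector, g_slope_at, growth_function
from .lifecycle import (
    DISABLED_KERNEL,
    LifeCycleParams,
    MutationKernel,
    PopulationState,
    Trajectory,
    population_from_colours,
    run_evolution,
)
from .particles import CollectiveState, ParticleType, adult_colour, simulate_growth

SCENARIOS = (
    "full_evolution",
    "neutral_collapse",
    "newborn_adult_map",
    "constrained_r",
    "constrained_ainter",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """A scenario plus everything needed to replay it."""

    scenario: str
    params: LifeCycleParams
    kernel: MutationKernel
    red: ParticleType
    blue: ParticleType
    seed: int = 0
    scale_D: float = 1.0
    scale_M: float = 1.0
    replicates: int = 50
    initial_colour: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    def scaled_params(self) -> LifeCycleParams:
        D = max(2, int(round(self.params.D * self.scale_D)))
        M = max(0, int(round(self.params.M * self.scale_M)))
        return replace(self.params, D=D, M=M)


def scenario_full_evolution(config: ScenarioConfig) -> Trajectory:
    """Whole-trajectory evolution experiment (neutral or selective regime)."""
    params = config.scaled_params()
    return run_evolution(
        params, config.red, config.blue, seed=config.seed, kernel=config.kernel
    )


def scenario_neutral_collapse(
    config: ScenarioConfig,
    initial_colours: np.ndarray | None = None,
) -> Trajectory:
    """Ecology-only run: mutation off, neutral extinction, prescribed colours.

    Probes whether a trait set maintains the collective phenotype without
    selection. ``initial_colours`` defaults to every collective founded at
    ``config.initial_colour`` (or ``phi_hat`` when unset), emulating a
    population that had already converged on the target before selection was
    removed.
    """
    params = replace(config.scaled_params(), regime="neutral")
    if initial_colours is None:
        phi = config.initial_colour
        phi = params.phi_hat if phi is None else phi
        initial_colours = np.full(params.D, float(phi))
    initial = population_from_colours(initial_colours, params.B, config.red, config.blue)
    return run_evolution(
        params, config.red, config.blue, seed=config.seed, kernel=DISABLED_KERNEL,
        initial=initial,
    )


def scenario_newborn_adult_map(
    red: ParticleType,
    blue: ParticleType,
    B: int,
    T: float,
    replicates: int = 50,
    phi_grid: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical newborn-to-adult colour map with the deterministic G overlay.

    For each grid colour phi, founds ``replicates`` collectives with
    ``round(phi * B)`` red particles, grows them for T and aggregates the
    adult colours. Columns: ``newborn_phi, mean_adult, sd_adult, n,
    g_deterministic``.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if phi_grid is None:
        phi_grid = np.linspace(0.0, 1.0, B + 1)
    spec = GrowthFunctionSpec(theta=TraitVector.from_types(red, blue), B=B, T=T)
    rows = []
    for k, phi in enumerate(np.asarray(phi_grid, dtype=float)):
        n_red = int(round(phi * B))
        adults = np.empty(replicates)
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), k, rep)))
            newborn = CollectiveState(populations=[
                (red, n_red), (blue, B - n_red),
            ])
            adults[rep] = adult_colour(simulate_growth(newborn, T, rng))
        rows.append({
            "newborn_phi": n_red / B,
            "mean_adult": float(adults.mean()),
            "sd_adult": float(adults.std(ddof=1)),
            "n": replicates,
            "g_deterministic": growth_function(n_red / B, spec),
        })
    return pd.DataFrame(rows)


def scenario_constrained(config: ScenarioConfig, diag_every: int = 10) -> tuple[Trajectory, pd.DataFrame]:
    """Evolution with a restricted mutation kernel (trade-off experiments).

    ``constrained_r``: only growth rates mutate and particles do not compete
    (all competition coefficients zero) -- growth rates are expected to
    align. ``constrained_ainter``: only the two inter-colour coefficients
    mutate while growth rates stay fixed -- the trait pair is expected to
    reach the optimality manifold G(phi_hat) = phi_hat and then flatten G.

    Returns the trajectory plus a diagnostics table sampled every
    ``diag_every`` generations with the population-mean resident traits and,
    for those traits, G(phi_hat) and |dG/dphi| at phi_hat.
    """
    if config.scenario == "constrained_r":
        expected = frozenset({"r"})
    elif config.scenario == "constrained_ainter":
        expected = frozenset({"a_inter"})
    else:
        raise ValueError("scenario must be constrained_r or constrained_ainter")
    if config.kernel.traits != expected:
        raise ValueError(f"kernel must mutate exactly {set(expected)} for {config.scenario}")

    params = config.scaled_params()
    traj = run_evolution(
        params, config.red, config.blue, seed=config.seed, kernel=config.kernel
    )
    rows = []
    gens = list(range(0, len(traj.records), diag_every))
    if gens and gens[-1] != len(traj.records) - 1:
        gens.append(len(traj.records) - 1)
    for g in gens:
        rec = traj.records[g]
        m = rec.resident_trait_means
        row = {"generation": rec.generation, **m}
        theta_kwargs = dict(
            r0=m["r_red"], r1=m["r_blue"],
            a00=m["a_intra_red"], a01=m["a_inter_blue"],
            a10=m["a_inter_red"], a11=m["a_intra_blue"],
        )
        if np.all(np.isfinite(list(theta_kwargs.values()))):
            theta = TraitVector(**theta_kwargs)
            spec = GrowthFunctionSpec(theta=theta, B=params.B, T=params.T)
            row["g_at_target"] = growth_function(params.phi_hat, spec)
            row["g_slope_at_target"] = abs(g_slope_at(params.phi_hat, spec))
        else:
            row["g_at_target"] = np.nan
            row["g_slope_at_target"] = np.nan
        rows.append(row)
    return traj, pd.DataFrame(rows)


def summarize_trajectory(traj: Trajectory) -> pd.DataFrame:
    """Per-generation summary table (pure aggregation of the records)."""
    return traj.to_dataframe()


def default_config(scenario: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """The published configuration of a scenario, at full scale.

    ``overrides`` may replace any :class:`ScenarioConfig` field (typically
    ``scale_D`` / ``scale_M`` for desk-scale runs).
    """
    if scenario in ("full_evolution", "neutral_collapse", "newborn_adult_map"):
        base = ScenarioConfig(
            scenario=scenario,
            params=defaults.STANDARD_PARAMS,
            kernel=defaults.DEFAULT_KERNEL if scenario == "full_evolution" else DISABLED_KERNEL,
            red=defaults.ANCESTRAL_RED,
            blue=defaults.ANCESTRAL_BLUE,
            seed=seed,
        )
    elif scenario == "constrained_r":
        base = ScenarioConfig(
            scenario=scenario,
            params=replace(defaults.STANDARD_PARAMS, M=300),
            kernel=MutationKernel(traits=frozenset({"r"}), sigma=0.05),
            red=ParticleType(colour="red", r=6.0, a_intra=0.0, a_inter=0.0),
            blue=ParticleType(colour="blue", r=5.0, a_intra=0.0, a_inter=0.0),
            seed=seed,
        )
    elif scenario == "constrained_ainter":
        base = ScenarioConfig(
            scenario=scenario,
            params=replace(defaults.STANDARD_PARAMS, M=300),
            kernel=MutationKernel(traits=frozenset({"a_inter"}), sigma=0.05),
            red=dataclasses.replace(defaults.ANCESTRAL_RED, r=25.0),
            blue=dataclasses.replace(defaults.ANCESTRAL_BLUE, r=25.0),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return replace(base, **overrides) if overrides else base
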