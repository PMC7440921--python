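"""Deterministic layer: competitive Lotka-Volterra ODE and the growth map G.

In the vanishing-noise (large carrying capacity) limit, the particle counts
``(x0, x1)`` of red and blue particles inside one collective follow

    dx0/dt = r0 x0 (1 - a00 x0 - a01 x1)
    dx1/dt = r1 x1 (1 - a10 x0 - a11 x1)

The *growth function* G maps the newborn colour phi (fraction of red) to the
adult colour obtained by integrating the ODE from real-valued initial masses
``(B phi, B (1 - phi))`` for a duration T. Its fixed points in [0, 1]
determine the long-run colour of a lineage across cycles of growth and
noise-free dilution (the staircase iteration), and how they move with the
bottleneck size B and generation duration T governs whether an experiment
can maintain a dichromatic community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .particles import ParticleType

#: |G(phi) - phi| below this everywhere means G is the identity map
IDENTITY_TOL = 1e-7


class DegenerateRegimeError(ValueError):
    """The interaction matrix is singular; no isolated interior equilibrium."""


@dataclass(frozen=True)
class TraitVector:
    """The six parameters theta of the deterministic system.

    ``a00`` (``a01``) is the per-capita effect of red (blue) particles on
    red; ``a10`` (``a11``) the effect of red (blue) on blue. In terms of
    particle traits: a00 = red a_intra, a01 = blue a_inter, a10 = red
    a_inter, a11 = blue a_intra.
    """

    r0: float
    r1: float
    a00: float
    a01: float
    a10: float
    a11: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.r1 > 0):
            raise ValueError("growth rates must be > 0")
        if min(self.a00, self.a01, self.a10, self.a11) < 0:
            raise ValueError("competition coefficients must be >= 0")

    @classmethod
    def from_types(cls, red: ParticleType, blue: ParticleType) -> "TraitVector":
        return cls(
            r0=red.r, r1=blue.r,
            a00=red.a_intra, a01=blue.a_inter,
            a10=red.a_inter, a11=blue.a_intra,
        )

    @property
    def carrying_capacities(self) -> tuple[float, float]:
        """Monoculture equilibria (K0, K1) = (1/a00, 1/a11); inf if a = 0."""
        k0 = 1.0 / self.a00 if self.a00 > 0 else np.inf
        k1 = 1.0 / self.a11 if self.a11 > 0 else np.inf
        return (k0, k1)


@dataclass(frozen=True)
class GrowthFunctionSpec:
    """Everything G depends on: traits theta, bottleneck B, duration T."""

    theta: TraitVector
    B: float
    T: float
    int_rtol: float = 1e-10
    int_atol: float = 1e-12
    fp_tol: float = 1e-8
    grid_n: int = 1001

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if min(self.int_rtol, self.int_atol, self.fp_tol) <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class FixedPointSet:
    """Fixed points of G with stability labels and a qualitative shape class.

    ``points`` always contains phi = 0 and phi = 1; interior points are
    sorted. ``shape_class`` is one of ``red_fixation`` (no interior root,
    phi = 1 stable), ``blue_fixation`` (no interior root, phi = 0 stable),
    ``interior_stable`` (one stable interior root), ``bistable`` (one
    unstable interior root separating two stable boundaries), ``identity``
    (degenerate G = id), or ``other`` (root list reported verbatim).
    """

    points: tuple  # of (phi, "stable" | "unstable" | "neutral")
    shape_class: str

    @property
    def interior(self) -> tuple:
        return tuple(p for p in self.points if 0.0 < p[0] < 1.0)

    def stable_interior(self) -> float | None:
        for phi, lab in self.interior:
            if lab == "stable":
                return phi
        return None


def lv_rhs(x0: float, x1: float, theta: TraitVector) -> tuple[float, float]:
    """Right-hand side of the competitive Lotka-Volterra system."""
    dx0 = theta.r0 * x0 * (1.0 - theta.a00 * x0 - theta.a01 * x1)
    dx1 = theta.r1 * x1 * (1.0 - theta.a10 * x0 - theta.a11 * x1)
    return dx0, dx1


def integrate_lv(
    x0: float,
    x1: float,
    theta: TraitVector,
    T: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[float, float]:
    """Numerical solution (x0(T), x1(T)); components stay >= 0."""
    if T < 0:
        raise ValueError("T must be >= 0")
    if T == 0:
        return float(x0), float(x1)

    def rhs(t, y):
        return lv_rhs(y[0], y[1], theta)

    sol = solve_ivp(rhs, (0.0, T), [float(x0), float(x1)], method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"LV integration failed: {sol.message}")
    out = np.clip(sol.y[:, -1], 0.0, None)
    return float(out[0]), float(out[1])


def growth_function(phi: float, spec: GrowthFunctionSpec) -> float:
    """Adult colour G(phi) after one deterministic growth phase."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    x0, x1 = integrate_lv(
        spec.B * phi, spec.B * (1.0 - phi), spec.theta, spec.T,
        rtol=spec.int_rtol, atol=spec.int_atol,
    )
    return x0 / (x0 + x1)


def growth_function_grid(phis: np.ndarray, spec: GrowthFunctionSpec) -> np.ndarray:
    """Vectorised G over a grid of newborn colours (one ensemble ODE solve).

    The grid initial conditions are integrated as a single decoupled system,
    which is much faster than one ``solve_ivp`` call per grid point and
    numerically equivalent at the ensemble tolerance (1e-8 relative).
    """
    phis = np.asarray(phis, dtype=float)
    th = spec.theta
    y0 = np.concatenate([spec.B * phis, spec.B * (1.0 - phis)])
    n = len(phis)

    def rhs(t, y):
        x0, x1 = y[:n], y[n:]
        return np.concatenate([
            th.r0 * x0 * (1.0 - th.a00 * x0 - th.a01 * x1),
            th.r1 * x1 * (1.0 - th.a10 * x0 - th.a11 * x1),
        ])

    sol = solve_ivp(rhs, (0.0, spec.T), y0, method="RK45", rtol=1e-8, atol=1e-10)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"LV ensemble integration failed: {sol.message}")
    x0 = np.clip(sol.y[:n, -1], 0.0, None)
    x1 = np.clip(sol.y[n:, -1], 0.0, None)
    return x0 / (x0 + x1)


def g_exponential_limit(phi: float, r0: float, r1: float, T: float) -> float:
    """Closed-form G in the non-interacting (exponential growth) limit."""
    num = phi * np.exp(r0 * T)
    return float(num / (num + (1.0 - phi) * np.exp(r1 * T)))


def coexistence_equilibrium(
    theta: TraitVector,
) -> tuple[str, float | None, tuple[float, float] | None]:
    """Classify the long-time LV regime and locate the interior equilibrium.

    Mutual invasibility decides the class: red invades a blue monoculture
    iff a01 < a11, blue invades red iff a10 < a00. Both give stable
    *coexistence*; neither, *bistability* (unstable interior point); exactly
    one, competitive *exclusion* by the invader. Where the interior
    equilibrium exists, the collective colour there is
    phi* = (a11 - a01) / ((a11 - a01) + (a00 - a10)).
    """
    if not (theta.a00 > 0 and theta.a11 > 0):
        raise ValueError("coexistence analysis requires a00 > 0 and a11 > 0")
    d0 = theta.a11 - theta.a01  # red invades blue iff > 0
    d1 = theta.a00 - theta.a10  # blue invades red iff > 0
    det = theta.a00 * theta.a11 - theta.a01 * theta.a10
    if d0 == 0 or d1 == 0 or det == 0:
        raise DegenerateRegimeError("degenerate interaction matrix")
    if d0 > 0 and d1 > 0:
        regime = "coexistence"
    elif d0 < 0 and d1 < 0:
        regime = "bistability"
    elif d0 > 0:
        regime = "exclusion_red_wins"
    else:
        regime = "exclusion_blue_wins"
    if regime.startswith("exclusion"):
        return regime, None, None
    x = np.linalg.solve(
        np.array([[theta.a00, theta.a01], [theta.a10, theta.a11]]),
        np.ones(2),
    )
    phi_star = d0 / (d0 + d1)
    return regime, float(phi_star), (float(x[0]), float(x[1]))


def find_fixed_points(spec: GrowthFunctionSpec, grid_n: int | None = None) -> FixedPointSet:
    """All roots of G(phi) - phi on [0, 1] with stability labels.

    Roots are bracketed by sign changes of ``G - id`` on a uniform grid
    (default 1e-3 resolution) and refined by Brent bisection to
    ``spec.fp_tol``. Stability follows the sign of the displacement
    ``G(phi) - phi`` on either side of the root: a + to - crossing is
    stable. phi = 0 and phi = 1 are always fixed points; their stability is
    read off the displacement at the adjacent grid point. A grid on which
    ``|G - id|`` never exceeds ``IDENTITY_TOL`` is reported as the
    degenerate identity class.
    """
    n = grid_n or spec.grid_n
    grid = np.linspace(0.0, 1.0, n)
    h = growth_function_grid(grid, spec) - grid

    if np.max(np.abs(h)) < IDENTITY_TOL:
        points = ((0.0, "neutral"), (1.0, "neutral"))
        return FixedPointSet(points=points, shape_class="identity")

    interior: list[tuple[float, str]] = []
    sign = np.sign(h)
    # treat exact zeros on the open interior as sign boundaries
    for k in range(1, n - 2):
        s_left, s_right = sign[k], sign[k + 1]
        if s_left == 0.0:
            interior.append((float(grid[k]), _stability(sign, k, n)))
            continue
        if s_left * s_right < 0:
            f = lambda p: growth_function(p, spec) - p
            root = brentq(f, grid[k], grid[k + 1], xtol=spec.fp_tol)
            label = "stable" if s_left > 0 else "unstable"
            interior.append((float(root), label))
    interior.sort()

    stab0 = "unstable" if h[1] > 0 else "stable"
    stab1 = "stable" if h[-2] > 0 else "unstable"
    points = tuple([(0.0, stab0)] + interior + [(1.0, stab1)])

    n_int = len(interior)
    if n_int == 0:
        shape = "red_fixation" if stab1 == "stable" else "blue_fixation"
    elif n_int == 1:
        shape = "interior_stable" if interior[0][1] == "stable" else "bistable"
    else:
        shape = "other"
    return FixedPointSet(points=points, shape_class=shape)


def _stability(sign: np.ndarray, k: int, n: int) -> str:
    left = sign[max(k - 1, 0)]
    right = sign[min(k + 1, n - 1)]
    if left > 0 and right < 0:
        return "stable"
    if left < 0 and right > 0:
        return "unstable"
    return "neutral"


@dataclass
class StaircaseResult:
    """Colour sequence from iterating phi <- G(phi)."""

    colours: list[float]
    reason: str  # fixation_red | fixation_blue | converged | max_iter

    @property
    def n_generations(self) -> int:
        """Number of G applications performed before the stop rule fired."""
        return len(self.colours) - 1


def staircase_iteration(
    phi0: float,
    spec: GrowthFunctionSpec,
    max_iter: int = 1000,
    conv_tol: float | None = None,
    fixation_rule: bool = True,
) -> StaircaseResult:
    """Iterate the deterministic growth-dilution cycle from colour ``phi0``.

    Stops at ``max_iter``, at convergence (|phi_{n+1} - phi_n| < conv_tol,
    default ``spec.fp_tol``) or, when ``fixation_rule`` is set, once the
    expected minority founder count drops below half a particle
    (``B * min(phi, 1 - phi) < 0.5``) -- the discretisation threshold at
    which a real bottleneck of B particles would fix the majority colour.
    """
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError("phi0 must lie in [0, 1]")
    tol = spec.fp_tol if conv_tol is None else conv_tol
    phi = float(phi0)
    colours = [phi]

    def fixated(p: float) -> str | None:
        if fixation_rule and spec.B * min(p, 1.0 - p) < 0.5:
            return "fixation_red" if p >= 0.5 else "fixation_blue"
        return None

    reason = fixated(phi)
    if reason is not None:
        return StaircaseResult(colours=colours, reason=reason)
    for _ in range(max_iter):
        nxt = growth_function(phi, spec)
        colours.append(float(nxt))
        reason = fixated(nxt)
        if reason is not None:
            break
        if abs(nxt - phi) < tol:
            reason = "converged"
            phi = nxt
            break
        phi = nxt
    else:
        reason = "max_iter"
    return StaircaseResult(colours=colours, reason=reason)


def g_slope_at(phi: float, spec: GrowthFunctionSpec, h: float = 1e-4) -> float:
    """dG/dphi by central finite difference (step clipped inside (0, 1))."""
    if not 0.0 < phi < 1.0:
        raise ValueError("slope is defined on the open interval (0, 1)")
    h = min(h, phi / 2, (1.0 - phi) / 2)
    hi = growth_function(phi + h, spec)
    lo = growth_function(phi - h, spec)
    return (hi - lo) / (2.0 * h)


def bt_phase_diagram(
    theta: TraitVector,
    B_grid: np.ndarray,
    T_grid: np.ndarray,
    grid_n: int = 401,
    fp_tol: float = 1e-8,
) -> pd.DataFrame:
    """Shape class and interior fixed point of G for every (B, T) cell.

    Returns one row per cell with columns ``B, T, shape_class,
    stable_interior, n_interior, phi0_stable, phi1_stable``;
    ``stable_interior`` is NaN when no stable interior fixed point exists.
    """
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        for B in np.asarray(B_grid, dtype=float):
            spec = GrowthFunctionSpec(theta=theta, B=B, T=T, fp_tol=fp_tol)
            fps = find_fixed_points(spec, grid_n=grid_n)
            stable = fps.stable_interior()
            labels = dict(fps.points)
            rows.append({
                "B": B,
                "T": T,
                "shape_class": fps.shape_class,
                "stable_interior": np.nan if stable is None else stable,
                "n_interior": len(fps.interior),
                "phi0_stable": labels.get(0.0) == "stable",
                "phi1_stable": labels.get(1.0) == "stable",
            })
    return pd.DataFrame(rows)


def stability_boundary(diagram: pd.DataFrame) -> pd.DataFrame:
    """Numerical boundary of the interior-stable region of a (B, T) scan.

    For each B column of the diagram, reports the smallest T whose cell has
    a stable interior fixed point (NaN when none does). This is the contour
    between cells with and without an interior stable point, at the
    resolution of the scanned grid.
    """
    rows = []
    for B, sub in diagram.groupby("B"):
        hit = sub.loc[sub["shape_class"] == "interior_stable", "T"]
        rows.append({"B": B, "T_min_stable": hit.min() if len(hit) else np.nan})
    return pd.DataFrame(rows).sort_values("B").reset_index(drop=True)
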