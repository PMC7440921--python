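"""Unit tests for the Lotka-Volterra growth-function toolkit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoscaffold import (
    GrowthFunctionSpec,
    TraitVector,
    bt_phase_diagram,
    coexistence_equilibrium,
    find_fixed_points,
    g_exponential_limit,
    g_slope_at,
    growth_function,
    growth_function_grid,
    integrate_lv,
    lv_rhs,
    staircase_iteration,
    stability_boundary,
)

K = 1500.0


def _spec(theta, B=15, T=1.0, **kw):
    return GrowthFunctionSpec(theta=theta, B=B, T=T, **kw)


class TestLVRhs:
    def test_origin_is_equilibrium(self, ancestral_theta):
        assert lv_rhs(0.0, 0.0, ancestral_theta) == (0.0, 0.0)

    def test_monoculture_carrying_capacity(self, ancestral_theta):
        dx0, _ = lv_rhs(1.0 / ancestral_theta.a00, 0.0, ancestral_theta)
        assert dx0 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self, ancestral_theta):
        dx0, dx1 = lv_rhs(1.0, 14.0, ancestral_theta)
        assert dx0 == pytest.approx(6 * (1 - (0.8 + 0.15 * 14) / K))
        assert dx0 == pytest.approx(5.9884)


class TestIntegrateLV:
    def test_logistic_closed_form(self):
        """Single type: logistic growth with K = 1/a."""
        theta = TraitVector(r0=6.0, r1=1.0, a00=0.8 / K, a01=0.0, a10=0.0, a11=1e-9)
        x0, _ = integrate_lv(15.0, 0.0, theta, 1.0)
        Kcap = K / 0.8  # 1875
        expected = Kcap / (1 + (Kcap / 15 - 1) * np.exp(-6.0))
        assert x0 == pytest.approx(expected, rel=1e-6)

    def test_exponential_limit_all_a_zero(self):
        theta = TraitVector(r0=2.0, r1=0.5, a00=0.0, a01=0.0, a10=0.0, a11=0.0)
        x0, x1 = integrate_lv(3.0, 7.0, theta, 1.5)
        assert x0 == pytest.approx(3 * np.exp(3.0), rel=1e-8)
        assert x1 == pytest.approx(7 * np.exp(0.75), rel=1e-8)

    def test_long_time_converges_to_coexistence_equilibrium(self, ancestral_theta):
        _, _, (x0s, x1s) = coexistence_equilibrium(ancestral_theta)
        x0, x1 = integrate_lv(10.0, 10.0, ancestral_theta, 30.0)
        assert x0 == pytest.approx(x0s, rel=1e-3)
        assert x1 == pytest.approx(x1s, rel=1e-3)

    def test_zero_duration(self, ancestral_theta):
        assert integrate_lv(3.0, 4.0, ancestral_theta, 0.0) == (3.0, 4.0)


class TestGrowthFunction:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        r0=st.floats(0.5, 10), r1=st.floats(0.5, 10),
        a00=st.floats(0, 0.03), a01=st.floats(0, 0.03),
        a10=st.floats(0, 0.03), a11=st.floats(0, 0.03),
    )
    def test_boundaries_are_fixed_points(self, r0, r1, a00, a01, a10, a11):
        """G(0) = 0 and G(1) = 1 for any trait vector."""
        spec = _spec(TraitVector(r0, r1, a00, a01, a10, a11), B=10, T=2.0)
        assert growth_function(0.0, spec) == pytest.approx(0.0, abs=1e-12)
        assert growth_function(1.0, spec) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_traits_fix_one_half(self):
        theta = TraitVector(r0=3.0, r1=3.0, a00=0.01, a01=0.004, a10=0.004, a11=0.01)
        assert growth_function(0.5, _spec(theta, B=20, T=2.0)) == pytest.approx(0.5, abs=1e-9)

    def test_ancestral_curve_above_diagonal(self, ancestral_spec):
        """Red gains within every dichromatic collective: G(phi) > phi."""
        phis = np.linspace(0.05, 0.95, 19)
        g = growth_function_grid(phis, ancestral_spec)
        assert (g > phis).all()

    def test_grid_matches_pointwise_evaluation(self, ancestral_spec):
        phis = np.array([0.1, 0.5, 0.9])
        g_grid = growth_function_grid(phis, ancestral_spec)
        g_pt = [growth_function(p, ancestral_spec) for p in phis]
        np.testing.assert_allclose(g_grid, g_pt, atol=1e-7)


class TestExponentialLimit:
    def test_equal_rates_identity(self):
        for phi in (0.0, 0.3, 1.0):
            assert g_exponential_limit(phi, 2.0, 2.0, 5.0) == pytest.approx(phi)

    def test_closed_form_value(self):
        assert g_exponential_limit(0.5, 6.0, 4.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-2.0))
        )
        assert g_exponential_limit(0.5, 6.0, 4.0, 1.0) == pytest.approx(0.880797, abs=1e-6)

    def test_growth_function_approaches_limit_as_a_vanishes(self):
        theta = TraitVector(r0=6.0, r1=4.0, a00=1e-12, a01=1e-12, a10=1e-12, a11=1e-12)
        spec = _spec(theta, B=15, T=1.0)
        phis = np.linspace(0.0, 1.0, 41)
        g = growth_function_grid(phis, spec)
        closed = np.array([g_exponential_limit(p, 6.0, 4.0, 1.0) for p in phis])
        assert np.max(np.abs(g - closed)) < 1e-6


class TestCoexistenceEquilibrium:
    def test_printed_trait_values(self, ancestral_theta):
        regime, phi_star, x_star = coexistence_equilibrium(ancestral_theta)
        assert regime == "coexistence"
        assert phi_star == pytest.approx(0.15 / 0.80)  # 0.1875
        # independent check: the equilibrium nulls the vector field
        dx0, dx1 = lv_rhs(x_star[0], x_star[1], ancestral_theta)
        assert abs(dx0) < 1e-9 and abs(dx1) < 1e-9

    def test_symmetric_traits_give_half(self):
        theta = TraitVector(r0=1.0, r1=1.0, a00=0.01, a01=0.002, a10=0.002, a11=0.01)
        _, phi_star, _ = coexistence_equilibrium(theta)
        assert phi_star == pytest.approx(0.5)

    def test_bistability_class_verified_by_integration(self):
        """a01 > a11 and a10 > a00: initial conditions decide the winner."""
        theta = TraitVector(r0=3.0, r1=3.0, a00=0.01, a01=0.02, a10=0.02, a11=0.01)
        regime, phi_star, _ = coexistence_equilibrium(theta)
        assert regime == "bistability" and phi_star == pytest.approx(0.5)
        x0a, x1a = integrate_lv(90.0, 10.0, theta, 200.0)
        x0b, x1b = integrate_lv(10.0, 90.0, theta, 200.0)
        assert x1a / (x0a + x1a) < 1e-6  # red-rich start: blue excluded
        assert x0b / (x0b + x1b) < 1e-6  # blue-rich start: red excluded

    def test_exclusion_class(self):
        theta = TraitVector(r0=3.0, r1=3.0, a00=0.01, a01=0.004, a10=0.02, a11=0.01)
        regime, phi_star, x_star = coexistence_equilibrium(theta)
        assert regime == "exclusion_red_wins"
        assert phi_star is None and x_star is None


class TestFindFixedPoints:
    def test_ancestral_standard_spec(self, ancestral_spec):
        """B=15, T=1 ancestral: red fixes; no interior root."""
        fps = find_fixed_points(ancestral_spec)
        assert fps.shape_class == "red_fixation"
        assert fps.interior == ()
        labels = dict(fps.points)
        assert labels[0.0] == "unstable" and labels[1.0] == "stable"

    def test_large_B_T_interior_root_near_phi_star(self, ancestral_theta):
        fps = find_fixed_points(_spec(ancestral_theta, B=1000, T=10.0))
        assert fps.shape_class == "interior_stable"
        assert fps.stable_interior() == pytest.approx(0.1875, abs=1e-4)

    def test_identity_map_reported_as_degenerate(self):
        theta = TraitVector(r0=2.0, r1=2.0, a00=0.0, a01=0.0, a10=0.0, a11=0.0)
        fps = find_fixed_points(_spec(theta, B=10, T=1.0), grid_n=201)
        assert fps.shape_class == "identity"

    def test_agrees_with_dense_scan_oracle(self):
        """Root finder vs brute-force dense sign scan on random trait sets."""
        rng = np.random.default_rng(99)
        for _ in range(6):
            theta = TraitVector(
                r0=rng.uniform(1, 8), r1=rng.uniform(1, 8),
                a00=rng.uniform(0.001, 0.03), a01=rng.uniform(0.001, 0.03),
                a10=rng.uniform(0.001, 0.03), a11=rng.uniform(0.001, 0.03),
            )
            spec = _spec(theta, B=10, T=2.0)
            fps = find_fixed_points(spec)
            # oracle: independent pointwise evaluations on a coarser grid
            grid = np.linspace(0.0, 1.0, 201)
            spacing = grid[1] - grid[0]
            h = np.array([growth_function(p, spec) - p for p in grid])
            inner = np.sign(h[1:-1])
            bracket_lo = grid[1:-1][:-1][inner[:-1] * inner[1:] < 0]
            found = np.array([phi for phi, _ in fps.interior])
            # every oracle bracket contains a found root
            for lo in bracket_lo:
                assert np.any((found >= lo) & (found <= lo + spacing))
            # every found root away from the boundaries is seen by the oracle,
            # and every found root is a genuine fixed point of G
            away = found[(found > 2 * spacing) & (found < 1 - 2 * spacing)]
            assert len(away) <= len(bracket_lo)
            for phi in found:
                assert abs(growth_function(phi, spec) - phi) < 1e-6


class TestStaircase:
    def test_constant_at_stable_fixed_point(self, ancestral_theta):
        spec = _spec(ancestral_theta, B=1000, T=10.0)
        fp = find_fixed_points(spec).stable_interior()
        res = staircase_iteration(fp, spec, max_iter=10, fixation_rule=False)
        assert max(abs(c - fp) for c in res.colours) < 1e-6

    def test_derived_traits_converge_to_target_from_anywhere(self, derived_theta):
        spec = _spec(derived_theta, B=15, T=1.0)
        for phi0 in (0.1, 0.9):
            res = staircase_iteration(phi0, spec, max_iter=20, fixation_rule=False)
            assert res.reason == "converged"
            assert res.colours[-1] == pytest.approx(0.5, abs=0.01)

    def test_fixation_stop_rule_from_boundary_start(self, ancestral_spec):
        res = staircase_iteration(0.999, ancestral_spec)
        assert res.reason == "fixation_red" and res.n_generations == 0


class TestGSlope:
    def test_identity_map_slope_one(self):
        theta = TraitVector(r0=2.0, r1=2.0, a00=0.0, a01=0.0, a10=0.0, a11=0.0)
        assert g_slope_at(0.4, _spec(theta, B=10, T=1.0)) == pytest.approx(1.0, abs=1e-6)

    def test_slope_below_one_at_stable_interior_point(self, derived_theta):
        spec = _spec(derived_theta, B=15, T=1.0)
        fp = find_fixed_points(spec).stable_interior()
        assert abs(g_slope_at(fp, spec)) < 1.0

    def test_asymmetric_competition_flattens_g(self):
        """Within the family of trait sets sharing phi* = 0.5 (a10 = a00 -
        a11 + a01), the slope of G at the fixed point shrinks monotonically
        as the inter-colour coefficient acting on the lower-carrying-capacity
        type goes to zero (canalisation by maximal asymmetry)."""
        slopes = []
        for a01 in (0.0, 0.1 / K, 0.2 / K):
            theta = TraitVector(r0=8.0, r1=8.0, a00=0.8 / K, a01=a01,
                                a10=0.5 / K + a01, a11=0.3 / K)
            slopes.append(abs(g_slope_at(0.5, _spec(theta, B=15, T=1.0))))
        assert slopes[0] < slopes[1] < slopes[2]


class TestPhaseDiagram:
    def test_corner_classes_and_boundary(self, ancestral_theta):
        B_grid = np.geomspace(2, 1000, 5)
        T_grid = np.geomspace(0.1, 10, 5)
        df = bt_phase_diagram(ancestral_theta, B_grid, T_grid, grid_n=201)
        assert len(df) == 25
        cell = lambda b, t: df[(df["B"] == b) & (df["T"] == t)].iloc[0]
        small = cell(B_grid[0], T_grid[0])
        big = cell(B_grid[-1], T_grid[-1])
        assert small["shape_class"] == "red_fixation" and small["phi1_stable"]
        assert big["shape_class"] == "interior_stable"
        assert big["stable_interior"] == pytest.approx(0.1875, abs=1e-3)
        bnd = stability_boundary(df)
        assert len(bnd) == 5
        # larger bottlenecks stabilise coexistence at shorter durations
        tmin = bnd["T_min_stable"].to_numpy()
        assert np.nanmin(tmin) == tmin[-1]

    def test_stable_region_monotone_along_T(self, ancestral_theta):
        df = bt_phase_diagram(
            ancestral_theta, np.geomspace(5, 500, 4), np.geomspace(0.2, 8, 6),
            grid_n=201,
        )
        for _, sub in df.groupby("B"):
            flags = (sub.sort_values("T")["shape_class"] == "interior_stable").astype(int)
            assert (np.diff(flags) >= 0).all()
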