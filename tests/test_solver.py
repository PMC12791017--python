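"""Coupled isotopologue boundary-value solver."""

import numpy as np
import pytest

from pyritize import NonDimensionalParams, SolverOptions, solve_profile
from pyritize.params import R_VCDT, delta_from_ratio, ratio_from_delta
from pyritize.solver import (
    delta_curves,
    find_zeta_max,
    flux_balance,
    msr_rate,
    solve_bulk,
)


class TestDegenerateLimits:
    def test_no_organic_carbon_means_no_reduction(self, fast_options):
        p = NonDimensionalParams(gamma0=0.0, da_star=2.0, psi0=0.0, eta0=0.01)
        sol = solve_profile(p, fast_options)
        np.testing.assert_allclose(sol.sigma, 1.0, atol=1e-6)
        np.testing.assert_allclose(sol.eta, 0.01, atol=1e-6)
        assert np.all(sol.pi == 0.0)

    def test_no_iron_means_no_pyrite(self, fast_options):
        p = NonDimensionalParams(gamma0=2.0, da_star=2.0, psi0=0.0)
        sol = solve_profile(p, fast_options)
        assert np.all(sol.pi == 0.0)
        assert sol.zeta_max == 0.0

    def test_no_sink_conserves_sulfur(self, fast_options):
        """Without iron, MSR production must leave as sulfide efflux or
        burial at every steady state."""
        p = NonDimensionalParams(gamma0=1.0, da_star=2.0, psi0=0.0)
        sol = solve_profile(p, fast_options)
        fb = flux_balance(p, sol)
        assert fb["pyrite_burial"] == 0.0
        assert fb["closure_error"] < 5e-3

    def test_unit_alpha_kills_fractionation(self, fast_options):
        p = NonDimensionalParams(gamma0=5.0, da_star=3.0, psi0=10.0, alpha34=1.0)
        sol = solve_profile(p, fast_options)
        sw = p.d34s_sulfate_sw
        np.testing.assert_allclose(sol.d34s_sulfate, sw, atol=0.01)
        finite = np.isfinite(sol.d34s_pyrite)
        np.testing.assert_allclose(sol.d34s_pyrite[finite], sw, atol=0.01)
        assert abs(sol.delta_pyrite) < 0.01


class TestSystemLimits:
    def test_open_system_expresses_equilibrium_fractionation(self, fast_options):
        """Infinite diffusive resupply pins porewater sulfate at seawater
        composition, so buried pyrite records the full equilibrium effect."""
        p = NonDimensionalParams(gamma0=0.01, da_star=100.0, psi0=10.0)
        sol = solve_profile(p, fast_options)
        eps = abs(1000.0 * (p.alpha34 - 1.0))
        assert sol.delta_pyrite == pytest.approx(eps, abs=2.0)

    def test_closed_system_dampens_fractionation(self, fast_options):
        """Quantitative sulfate consumption and capture returns the
        seawater composition to the buried pyrite (mass balance)."""
        p = NonDimensionalParams(gamma0=50.0, da_star=0.05, psi0=50.0)
        sol = solve_profile(p, fast_options)
        assert abs(sol.delta_pyrite) < 5.0


class TestConservation:
    def test_isotopologue_sums_match_bulk(
        self, glacial_solution, interglacial_solution, midrange_solution
    ):
        for _, sol in (glacial_solution, interglacial_solution, midrange_solution):
            assert sol.diagnostics["isotopologue_sum_error_sigma"] < 1e-6
            assert sol.diagnostics["isotopologue_sum_error_eta"] < 1e-6

    def test_flux_balance_on_random_draws(self, fast_options):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            p = NonDimensionalParams(
                gamma0=10 ** rng.uniform(-1, np.log10(50)),
                da_star=10 ** rng.uniform(np.log10(0.05), np.log10(50)),
                psi0=rng.uniform(0.0, 50.0),
            )
            sol = solve_profile(p, fast_options)
            assert flux_balance(p, sol)["closure_error"] < 5e-3

    def test_delta_pyrite_bounded_by_equilibrium_effect(self, fast_options):
        rng = np.random.default_rng(99)
        eps = abs(1000.0 * (NonDimensionalParams(1, 1, 1).alpha34 - 1.0))
        for _ in range(15):
            p = NonDimensionalParams(
                gamma0=10 ** rng.uniform(-1, np.log10(50)),
                da_star=10 ** rng.uniform(np.log10(0.05), np.log10(50)),
                psi0=rng.uniform(0.5, 50.0),
            )
            sol = solve_profile(p, fast_options)
            if np.isfinite(sol.delta_pyrite):
                assert -3.0 <= sol.delta_pyrite <= eps + 2.0

    def test_sulfate_distills_heavy_with_depth(self, glacial_solution):
        _, sol = glacial_solution
        d = sol.d34s_sulfate[np.isfinite(sol.d34s_sulfate)]
        assert np.all(np.diff(d) >= -0.01)


class TestSolutionStructure:
    def test_invariant_shapes(self, glacial_solution):
        p, sol = glacial_solution
        assert np.all(sol.sigma <= 1.0 + 1e-8) and np.all(np.diff(sol.sigma) <= 1e-8)
        assert np.all(sol.eta >= 0.0)
        assert sol.pi[0] == 0.0 and np.all(np.diff(sol.pi) >= 0.0)
        # pyrite cannot exceed decayed iron in sulfide-equivalent units
        assert np.all(sol.pi <= (p.psi0 - sol.psi) + 1e-8)

    def test_deep_boundary_placement_is_immaterial(self, fast_options):
        """Extending the domain cap from 5 to 10 changes the formation-zone
        outputs negligibly once iron decay has run to completion above
        the cap (fast pyritization case)."""
        p = NonDimensionalParams(gamma0=5.0, da_star=2.0, psi0=5.0, chi=10.0)
        s5 = solve_profile(p, fast_options)
        opts10 = SolverOptions(tol=fast_options.tol, zeta_cap=10.0)
        s10 = solve_profile(p, opts10)
        pi5_at = np.interp(5.0, s10.zeta, s10.pi)
        assert pi5_at == pytest.approx(s5.pi[-1], rel=2e-3)
        dpy10 = p.d34s_sulfate_sw - np.interp(5.0, s10.zeta, s10.d34s_pyrite)
        assert dpy10 == pytest.approx(s5.delta_pyrite, abs=1.0)

    def test_bulk_solve_alone(self, fast_options):
        p = NonDimensionalParams(gamma0=3.0, da_star=2.0, psi0=5.0)
        bulk = solve_bulk(p, fast_options)
        assert bulk.status == 0
        assert bulk.y[0, 0] == pytest.approx(1.0)

    def test_psi0_insensitivity_of_delta_pyrite(self, fast_options):
        """Iron delivery moves pyrite content strongly but the isotopic
        offset barely, outside the extreme-sequestration corner."""
        for g, d in [(25.2, 3.7), (3.9, 11.4), (8.0, 4.0)]:
            deltas = []
            for psi0 in (1.0, 10.0):
                p = NonDimensionalParams(gamma0=g, da_star=d, psi0=psi0)
                deltas.append(solve_profile(p, fast_options).delta_pyrite)
            assert abs(deltas[0] - deltas[1]) < 5.0


class TestZetaMax:
    def test_no_formation_zone(self):
        zeta = np.linspace(0, 5, 50)
        assert find_zeta_max(zeta, np.zeros(50), 5e-4) == 0.0

    def test_monotone_in_threshold(self, midrange_solution):
        # lowering the threshold can only push the formation-zone base deeper
        _, sol = midrange_solution
        prev = 0.0
        for beta in [1e-1, 1e-2, 1e-3, 5e-4, 1e-4]:
            z = find_zeta_max(sol.zeta, sol.dpi_dzeta, beta)
            assert z >= prev - 1e-12
            prev = z

    def test_threshold_after_peak_only(self):
        # rate starts below beta, peaks, then drops below: zeta_max is the
        # post-peak crossing, not the surface
        zeta = np.linspace(0, 5, 501)
        rate = np.exp(-((zeta - 1.0) ** 2) / 0.05)
        zmax = find_zeta_max(zeta, rate, 1e-3)
        assert 1.5 < zmax < 2.5

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            find_zeta_max(np.array([]), np.array([]), 5e-4)
        with pytest.raises(ValueError):
            find_zeta_max(np.array([0.0]), np.array([0.0]), -1.0)


class TestDeltaCurves:
    def test_vcdt_ratio_is_zero(self):
        d = delta_curves(np.array([1.0]), np.array([R_VCDT]))
        assert d[0] == pytest.approx(0.0)

    def test_boundary_is_seawater(self, glacial_solution):
        p, sol = glacial_solution
        assert sol.d34s_sulfate[0] == pytest.approx(28.0, abs=1e-6)

    def test_zero_light_isotopologue_is_nan(self):
        d = delta_curves(np.array([0.0, 1.0]), np.array([0.1, 0.1]))
        assert np.isnan(d[0]) and np.isfinite(d[1])


def test_msr_rate_positive_where_sulfate_remains(midrange_solution):
    p, sol = midrange_solution
    rate = msr_rate(p, sol.zeta, sol.sigma)
    assert np.all(rate >= 0.0)
    assert rate[0] > 0.0
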