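"""Tests of invasion fitness, PIP semantics, singular-strategy
classification and the trait-substitution machinery."""

import numpy as np
import pytest

import mixoevolve as mx
from mixoevolve.adaptive import PIP_CATEGORIES


class TestInvasionFitness:
    def test_zero_on_diagonal_for_viable_residents(self, any_tradeoff):
        """A resident at its own equilibrium has exactly zero per-capita
        growth: |lambda(theta, theta)| < 1e-8 on a 21-point grid."""
        p = any_tradeoff
        for theta in np.linspace(0.0, 1.0, 21):
            theta = float(theta)
            eq = mx.find_resident_equilibrium(theta, 20.0, p)
            if not eq.viable:
                continue
            assert abs(mx.invasion_fitness(theta, theta, 20.0, p,
                                           resident_eq=eq)) < 1e-8

    def test_nonviable_resident_reduces_to_empty_environment(self, specialist):
        # theta_res=1 cannot persist at 13 degC
        for theta_mut in (0.0, 0.3, 0.9):
            lam = mx.invasion_fitness(theta_mut, 1.0, 13.0, specialist)
            assert lam == pytest.approx(
                mx.empty_environment_growth(theta_mut, 13.0, specialist),
                abs=1e-12)

    def test_flat_landscape_at_linear_tradeoff_interior_ess(self, linear):
        """Where the linear trade-off admits an interior singular strategy the
        whole mutant fitness landscape collapses to zero."""
        points = mx.find_singular_points(18.0, linear)
        interior = [s for s in points if 0.0 < s.theta_star < 1.0]
        assert len(interior) == 1
        assert interior[0].classification == "neutral"
        theta_star = interior[0].theta_star
        eq = mx.find_resident_equilibrium(theta_star, 18.0, linear)
        lams = [mx.invasion_fitness(float(tm), theta_star, 18.0, linear,
                                    resident_eq=eq)
                for tm in np.linspace(0.0, 1.0, 101)]
        assert max(abs(l) for l in lams) < 1e-6


class TestSelectionGradient:
    def test_matches_two_point_oracle(self, generalist):
        theta, T = 0.4, 20.0
        eq = mx.find_resident_equilibrium(theta, T, generalist)
        delta = 1e-6
        oracle = (mx.invasion_fitness(theta + delta, theta, T, generalist,
                                      resident_eq=eq)
                  - mx.invasion_fitness(theta - delta, theta, T, generalist,
                                        resident_eq=eq)) / (2 * delta)
        grad = mx.selection_gradient(theta, T, generalist)
        assert grad == pytest.approx(oracle, rel=1e-4)

    def test_sign_flips_across_specialist_repeller(self, specialist):
        """The concave trade-off's interior singular point repels: the
        gradient is negative below it and positive above it."""
        repeller = [s for s in mx.find_singular_points(18.0, specialist)
                    if s.classification == "repeller"][0]
        th = repeller.theta_star
        lo = mx.selection_gradient(0.3, 18.0, specialist)
        hi = mx.selection_gradient(0.99, 18.0, specialist)
        assert 0.3 < th < 0.99
        assert lo < 0.0 < hi

    def test_nonviable_resident_raises(self, specialist):
        with pytest.raises(mx.NonviableResidentError):
            mx.selection_gradient(1.0, 13.0, specialist)


class TestPIP:
    def test_diagonal_never_invades_and_categories_well_formed(self, generalist):
        pip = mx.compute_pip(20.0, generalist, grid_n=21)
        assert set(np.unique(pip.category)) <= {0, 1, 2, 3}
        for j in range(21):
            name = pip.category_name(j, j)
            assert name != "mutant_invades"
        assert PIP_CATEGORIES[0] == "mutant_invades"

    def test_specialist_13C_region_topology(self, specialist):
        """At 13 degC mid- and high-investment residents are non-viable (gray
        columns); on the viable photosynthetic flank selection points down:
        less phagotrophic mutants invade, more phagotrophic ones are
        excluded."""
        pip = mx.compute_pip(13.0, specialist, grid_n=41)
        thetas = pip.theta_res_grid
        for res in (0.4, 0.95):  # inside the non-viable band
            j_gray = int(np.argmin(abs(thetas - res)))
            assert all(pip.category[i, j_gray] in (2, 3) for i in range(41))
        j = int(np.argmin(abs(thetas - 0.1)))  # viable, below the repeller
        i_down = int(np.argmin(abs(thetas - 0.025)))
        i_up = int(np.argmin(abs(thetas - 0.2)))
        assert pip.category_name(i_down, j) == "mutant_invades"
        assert pip.category_name(i_up, j) == "mutant_excluded"

    def test_linear_23C_selects_full_phagotrophy(self, linear):
        pip = mx.compute_pip(23.0, linear, grid_n=41)
        thetas = pip.theta_res_grid
        j = int(np.argmin(abs(thetas - 0.5)))
        i_up = int(np.argmin(abs(thetas - 0.9)))
        i_down = int(np.argmin(abs(thetas - 0.1)))
        assert pip.category_name(i_up, j) == "mutant_invades"
        assert pip.category_name(i_down, j) == "mutant_excluded"

    def test_pip_sign_agrees_with_substitution_direction(self, generalist):
        """If a invades b and b cannot invade a, the substitution sequence
        started at b moves toward a (sampled pairs)."""
        T = 20.0
        for res, mut in ((0.3, 0.5), (0.99, 0.9)):
            lam_ab = mx.invasion_fitness(mut, res, T, generalist)
            lam_ba = mx.invasion_fitness(res, mut, T, generalist)
            if lam_ab > 0 > lam_ba:
                end = mx.ess_attractor(T, generalist, res)
                assert abs(end - mut) < abs(end - res) or \
                    (min(res, mut) <= end <= max(res, mut))

    def test_small_grid_rejected(self, linear):
        with pytest.raises(ValueError):
            mx.compute_pip(20.0, linear, grid_n=2)


class TestSingularPoints:
    def test_specialist_repeller_with_bistable_boundaries(self, specialist):
        points = mx.find_singular_points(18.0, specialist)
        kinds = [p.classification for p in points]
        assert kinds.count("repeller") == 1
        boundaries = sorted(p.theta_star for p in points
                            if p.classification == "boundary_attractor")
        assert boundaries == [0.0, 1.0]
        repeller = points[[k == "repeller" for k in kinds].index(True)]
        assert not repeller.convergence_stable
        assert repeller.second_derivative > 0.0

    def test_no_specialist_branching_in_simulated_range(self, specialist):
        """Across 13-33 degC the specialist's interior singularity stays a
        repeller; branching does not occur in this temperature window."""
        for T in (13.0, 23.0, 33.0):
            interior = [p for p in mx.find_singular_points(T, specialist)
                        if 0.0 < p.theta_star < 1.0]
            assert {p.classification for p in interior} == {"repeller"}

    def test_specialist_branching_point_emerges_at_extreme_temperature(
            self, specialist):
        """Far above the ecological range the concave trade-off gains a
        convergence-stable but evolutionarily unstable singularity — a
        branching point flanked by two repellers."""
        points = mx.find_singular_points(95.0, specialist)
        kinds = [p.classification for p in points
                 if 0.0 < p.theta_star < 1.0]
        assert "branching_point" in kinds
        assert kinds.count("repeller") == 2
        branching = [p for p in points
                     if p.classification == "branching_point"][0]
        assert branching.convergence_stable
        assert not branching.evolutionarily_stable

    def test_generalist_interior_ess(self, generalist):
        points = [p for p in mx.find_singular_points(18.0, generalist)
                  if 0.0 < p.theta_star < 1.0]
        assert len(points) == 1
        ess = points[0]
        assert ess.classification == "ESS"
        assert ess.convergence_stable and ess.evolutionarily_stable
        assert 0.0 < ess.theta_star < 1.0

    def test_classification_invariants(self, specialist, generalist):
        for p, T in ((specialist, 18.0), (specialist, 95.0),
                     (generalist, 18.0)):
            for s in mx.find_singular_points(T, p):
                if s.classification == "branching_point":
                    assert s.convergence_stable and not s.evolutionarily_stable
                if s.classification == "repeller":
                    assert not s.convergence_stable

    def test_ess_uninvadable_globally(self, generalist):
        """No mutant anywhere on [0,1] invades the generalist ESS."""
        ess = [p for p in mx.find_singular_points(18.0, generalist)
               if p.classification == "ESS"][0]
        eq = mx.find_resident_equilibrium(ess.theta_star, 18.0, generalist)
        for tm in np.linspace(0.0, 1.0, 101):
            assert mx.invasion_fitness(float(tm), ess.theta_star, 18.0,
                                       generalist, resident_eq=eq) <= 1e-8


class TestTraitSubstitution:
    def test_generalist_ess_curve_rises_then_falls(self, generalist):
        curve = mx.ess_curve(range(13, 34), generalist)
        thetas = [c.attractors[0] for c in curve]
        peak = int(np.argmax(thetas))
        assert 0 < peak < len(thetas) - 1
        assert thetas[0] < thetas[peak] > thetas[-1]
        # interior mixotrophy across the whole range
        assert all(0.0 < t < 1.0 for t in thetas)

    def test_substitution_endpoint_matches_singular_point(self, generalist):
        ess = [p for p in mx.find_singular_points(20.0, generalist)
               if p.classification == "ESS"][0]
        end = mx.ess_attractor(20.0, generalist, 0.1)
        assert end == pytest.approx(ess.theta_star, abs=1e-3)

    def test_specialist_bistability_and_viability_onset(self, specialist):
        curve = mx.ess_curve(range(13, 34), specialist)
        for point in curve:
            assert set(point.attractors) <= {0.0, 1.0}
        lower_viable = [c.viable[0] for c in curve]
        upper_viable = {c.T: c.viable[1] for c in curve}
        assert all(lower_viable)
        assert not upper_viable[13] and not upper_viable[17]
        assert all(upper_viable[T] for T in range(18, 34))

    def test_linear_tradeoff_shifts_to_full_phagotrophy_near_19C(self, linear):
        """The linear trade-off's attractor leaves theta=0 once grazing on
        untouched prey outpays marginal photosynthesis (just below 18 degC)
        and reaches full phagotrophy within a grid step of 19 degC."""
        curve = {c.T: c.attractors[0] for c in mx.ess_curve(range(13, 34),
                                                            linear)}
        assert curve[17] == 0.0
        assert curve[18] > 0.0
        first_full = next(T for T in range(13, 34) if curve[T] == 1.0)
        assert abs(first_full - 19) <= 1

    def test_evolution_is_not_biomass_maximizing(self, generalist):
        """At high temperature the evolved strategy undershoots the
        population-maximizing strategy."""
        T = 33.0
        theta_ess = mx.ess_attractor(T, generalist, 0.8)
        M_ess = mx.find_resident_equilibrium(theta_ess, T, generalist).M_star
        best = max(mx.find_resident_equilibrium(float(t), T, generalist).M_star
                   for t in np.linspace(0.0, 1.0, 21))
        assert M_ess < best * (1 - 1e-6)

    def test_invalid_inputs(self, linear):
        with pytest.raises(ValueError):
            mx.ess_attractor(20.0, linear, 1.5)
        with pytest.raises(ValueError):
            mx.ess_curve([20.0, 15.0], linear)
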