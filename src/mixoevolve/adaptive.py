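"""Adaptive dynamics of the phagotrophic investment trait.

Evolution is modeled as a trait-substitution sequence: the resident strategy
sets the ecological equilibrium, rare mutants appear one at a time, and a
mutant whose invasion fitness (per-capita growth in the resident's
environment) is positive replaces the resident.  This module provides

* :func:`invasion_fitness` — the mutant growth rate λ(θ_mut, θ_res) at the
  resident's steady state (λ = empty-environment growth when the resident is
  itself non-viable);
* :func:`selection_gradient` — ∂λ/∂θ_mut at θ_mut = θ_res, by central finite
  differences;
* :func:`compute_pip` — pairwise invasibility plots with the viability
  (gray-region) categories;
* :func:`find_singular_points` — location and second-order classification of
  evolutionarily singular strategies (ESS / branching point / repeller /
  neutral), plus attracting boundaries;
* :func:`ess_attractor` / :func:`ess_curve` — the substitution-sequence
  endpoint for one temperature and its continuation along a temperature grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .equilibrium import (EquilibriumResult, empty_environment_growth,
                          find_resident_equilibrium)
from .model import ModelParams, depth_avg_photo_growth, grazing_growth

__all__ = [
    "PIPGrid",
    "SingularPoint",
    "ESSCurvePoint",
    "NonviableResidentError",
    "mutant_growth",
    "invasion_fitness",
    "selection_gradient",
    "compute_pip",
    "find_singular_points",
    "ess_attractor",
    "ess_curve",
]

log = logging.getLogger(__name__)

GRADIENT_STEP = 1e-5     # finite-difference step for the selection gradient
CURVATURE_STEP = 1e-3    # step for the second derivative of fitness
CURVATURE_TOL = 1e-6     # |d²λ| below this counts as a flat (neutral) landscape
SUBSTITUTION_STEP = 1e-3
SUBSTITUTION_SCAN = 1e-4
MAX_SUBSTITUTIONS = 100_000
# λ below this magnitude is equilibrium-solver noise, not positive fitness;
# keeps the PIP diagonal (λ(θ,θ)=0) from flickering into the invasion region
PIP_FITNESS_TOL = 1e-10

PIP_CATEGORIES = ("mutant_invades", "mutant_excluded",
                  "resident_nonviable_mutant_viable", "mutant_nonviable")


class NonviableResidentError(ValueError):
    """Raised when an operation requires a viable resident population."""


@dataclass(frozen=True)
class PIPGrid:
    """Categorized invasion-fitness sign structure over (θ_res, θ_mut).

    ``category[i, j]`` is the cell for mutant ``theta_mut_grid[i]`` against
    resident ``theta_res_grid[j]`` (mutant on rows ⇒ y-axis when imaged).
    Values index :data:`PIP_CATEGORIES`.
    """

    theta_res_grid: np.ndarray
    theta_mut_grid: np.ndarray
    category: np.ndarray  # int8 matrix, mutants × residents
    T: float

    def category_name(self, i: int, j: int) -> str:
        return PIP_CATEGORIES[self.category[i, j]]


@dataclass(frozen=True)
class SingularPoint:
    """An evolutionarily singular strategy (zero selection gradient) or an
    attracting boundary.

    ``classification`` ∈ {"ESS", "branching_point", "repeller", "neutral",
    "boundary_attractor"}; the boundary case reports θ ∈ {0, 1} where the
    one-sided gradient points into the boundary and carries no second-order
    flags.
    """

    theta_star: float
    T: float
    evolutionarily_stable: bool
    convergence_stable: bool
    classification: str
    second_derivative: float = float("nan")


@dataclass(frozen=True)
class ESSCurvePoint:
    """Substitution-sequence endpoints at one temperature.

    ``attractors`` may hold two entries for concave (specialist) trade-offs,
    whose interior repeller makes the boundaries bistable; ``viable`` flags
    each attractor's ecological feasibility.
    """

    T: float
    attractors: tuple
    viable: tuple


def mutant_growth(theta_mut: float, T: float, M: float, B: float,
                  params: ModelParams) -> float:
    """Per-capita growth of a rare mutant in an arbitrary environment (M, B)."""
    return (depth_avg_photo_growth(theta_mut, T, M, params)
            + grazing_growth(theta_mut, T, B, params)
            - params.l)


def invasion_fitness(theta_mut: float, theta_res: float, T: float,
                     params: ModelParams,
                     resident_eq: EquilibriumResult | None = None) -> float:
    """Invasion fitness λ(θ_mut, θ_res), d⁻¹.

    Evaluated at the resident's ecological equilibrium; a non-viable resident
    leaves the environment empty (M*=0, B*=K_B), so λ reduces to the
    empty-environment growth of the mutant.  ``resident_eq`` may be passed to
    amortize the equilibrium solve across many mutants.
    """
    if resident_eq is None:
        resident_eq = find_resident_equilibrium(theta_res, T, params)
    return mutant_growth(theta_mut, T, resident_eq.M_star, resident_eq.B_star,
                         params)


def selection_gradient(theta_res: float, T: float, params: ModelParams,
                       step: float = GRADIENT_STEP,
                       resident_eq: EquilibriumResult | None = None) -> float:
    """∂λ/∂θ_mut at θ_mut = θ_res (central difference; one-sided at 0 and 1).

    Raises :class:`NonviableResidentError` if the resident cannot persist —
    there is no resident environment in which to measure selection.
    """
    if resident_eq is None:
        resident_eq = find_resident_equilibrium(theta_res, T, params)
    if not resident_eq.viable:
        raise NonviableResidentError(
            f"resident theta={theta_res} is not viable at T={T} degC")
    lo = max(0.0, theta_res - step)
    hi = min(1.0, theta_res + step)
    lam = lambda th: mutant_growth(th, T, resident_eq.M_star,
                                   resident_eq.B_star, params)
    return (lam(hi) - lam(lo)) / (hi - lo)


def _fitness_curvature(theta_star: float, T: float, params: ModelParams,
                       eq: EquilibriumResult,
                       step: float = CURVATURE_STEP) -> float:
    """Second derivative of λ in the mutant direction at a singular point."""
    lo = max(0.0, theta_star - step)
    hi = min(1.0, theta_star + step)
    lam = lambda th: mutant_growth(th, T, eq.M_star, eq.B_star, params)
    # non-uniform 3-point stencil (handles clipping at the boundaries)
    d1, d2 = theta_star - lo, hi - theta_star
    f0, fl, fh = lam(theta_star), lam(lo), lam(hi)
    return 2.0 * (d1 * fh + d2 * fl - (d1 + d2) * f0) / (d1 * d2 * (d1 + d2))


def compute_pip(T: float, params: ModelParams, grid_n: int = 101) -> PIPGrid:
    """Rasterize the pairwise invasibility plot on a ``grid_n``² lattice.

    Categories follow the standard PIP reading: solid regions where the
    mutant invades a viable resident, white where it is excluded, and two
    gray-region flavors where the resident is non-viable — the mutant either
    can colonize the empty environment or cannot persist at all.
    """
    if grid_n < 3:
        raise ValueError(f"grid_n must be at least 3, got {grid_n}")
    thetas = np.linspace(0.0, 1.0, grid_n)
    category = np.empty((grid_n, grid_n), dtype=np.int8)
    for j, th_res in enumerate(thetas):
        eq = find_resident_equilibrium(th_res, T, params)
        for i, th_mut in enumerate(thetas):
            lam = mutant_growth(th_mut, T, eq.M_star, eq.B_star, params)
            if eq.viable:
                category[i, j] = 0 if lam > PIP_FITNESS_TOL else 1
            else:
                category[i, j] = 2 if lam > 0.0 else 3
    return PIPGrid(theta_res_grid=thetas, theta_mut_grid=thetas,
                   category=category, T=T)


def find_singular_points(T: float, params: ModelParams,
                         grid_n: int = 201) -> list[SingularPoint]:
    """Locate and classify singular strategies over the viable trait range.

    The gradient of the *extended* invasion fitness — λ evaluated in the
    empty environment wherever the resident is non-viable, exactly as in the
    PIP — is scanned on a ``grid_n``-point grid; sign changes are refined by
    bisection.  (The extension matters: for concave trade-offs the interior
    repeller can sit inside the non-viable gray band.)  Classification uses
    the standard second-order conditions: convergence stability from the
    gradient decreasing through zero across residents, evolutionary stability
    from the mutant-direction curvature of λ.  Attracting boundaries (the
    one-sided gradient pointing outward at θ=0 or θ=1) are appended as
    ``boundary_attractor`` entries.
    """
    thetas = np.linspace(0.0, 1.0, grid_n)
    points: list[SingularPoint] = []

    def gradient(theta_res: float) -> float:
        eq = find_resident_equilibrium(theta_res, T, params)
        lo = max(0.0, theta_res - GRADIENT_STEP)
        hi = min(1.0, theta_res + GRADIENT_STEP)
        lam = lambda th: mutant_growth(th, T, eq.M_star, eq.B_star, params)
        return (lam(hi) - lam(lo)) / (hi - lo)

    grads = np.array([gradient(min(max(t, GRADIENT_STEP), 1.0 - GRADIENT_STEP))
                      for t in thetas])

    for i in range(grid_n - 1):
        g1, g2 = grads[i], grads[i + 1]
        if g1 == 0.0 or np.sign(g1) == np.sign(g2):
            continue
        lo = min(max(thetas[i], GRADIENT_STEP), 1.0 - GRADIENT_STEP)
        hi = min(max(thetas[i + 1], GRADIENT_STEP), 1.0 - GRADIENT_STEP)
        theta_star = brentq(gradient, lo, hi, xtol=1e-10)
        eq = find_resident_equilibrium(theta_star, T, params)
        curvature = _fitness_curvature(theta_star, T, params, eq)
        convergence_stable = g1 > 0.0 > g2
        if abs(curvature) < CURVATURE_TOL:
            classification = "neutral"
            ess_flag = False
        elif not convergence_stable:
            classification = "repeller"
            ess_flag = curvature < 0.0
        elif curvature < 0.0:
            classification, ess_flag = "ESS", True
        else:
            classification, ess_flag = "branching_point", False
        points.append(SingularPoint(theta_star=theta_star, T=T,
                                    evolutionarily_stable=ess_flag,
                                    convergence_stable=convergence_stable,
                                    classification=classification,
                                    second_derivative=curvature))

    # attracting boundaries
    for boundary, inward in ((0.0, grads[0]), (1.0, grads[-1])):
        attracting = inward < 0.0 if boundary == 0.0 else inward > 0.0
        if attracting:
            points.append(SingularPoint(theta_star=boundary, T=T,
                                        evolutionarily_stable=True,
                                        convergence_stable=True,
                                        classification="boundary_attractor"))
    return points


def _local_improving_mutant(theta: float, T: float, eq: EquilibriumResult,
                            params: ModelParams, resolution: float):
    """First mutant within ±SUBSTITUTION_STEP of θ (at ``resolution``) with λ>0."""
    offsets = np.arange(resolution, SUBSTITUTION_STEP + resolution / 2, resolution)
    for d in offsets:
        for cand in (theta + d, theta - d):
            if 0.0 <= cand <= 1.0 and cand != theta:
                if mutant_growth(cand, T, eq.M_star, eq.B_star, params) > 0.0:
                    return cand
    return None


def ess_attractor(T: float, params: ModelParams, theta_init: float,
                  step: float = SUBSTITUTION_STEP,
                  scan: float = SUBSTITUTION_SCAN) -> float:
    """Run the trait-substitution sequence to its endpoint.

    From ``theta_init`` the trait moves in steps of ``step`` as long as the
    stepped mutant invades; once stuck, a local scan at ``scan`` resolution
    looks for any remaining improving mutant.  On a perfectly flat landscape
    (linear trade-off at its interior singular point) invasion is neutral to
    numerical noise, so a two-cycle (A→B→A) terminates the sequence.  Interior
    endpoints are polished by bisecting the selection gradient inside the last
    step so the reported strategy sits on the singular point itself.
    """
    if not 0.0 <= theta_init <= 1.0:
        raise ValueError(f"theta_init must lie in [0, 1], got {theta_init!r}")
    theta = theta_init
    previous = None
    for _ in range(MAX_SUBSTITUTIONS):
        eq = find_resident_equilibrium(theta, T, params)
        if not eq.viable:
            # Empty environment: with every nearby mutant also non-viable the
            # sequence follows the direction of improving (still negative)
            # growth, drifting toward the viable region if one is adjacent.
            candidate = None
            for d in (step, -step, scan, -scan):
                cand = min(1.0, max(0.0, theta + d))
                if cand != theta and (empty_environment_growth(cand, T, params)
                                      > empty_environment_growth(theta, T, params)):
                    candidate = cand
                    break
            if candidate is None:
                return theta
            theta = candidate
            continue
        candidate = None
        for d in (step, -step):
            cand = min(1.0, max(0.0, theta + d))
            if cand != theta and mutant_growth(cand, T, eq.M_star, eq.B_star,
                                               params) > 0.0:
                candidate = cand
                break
        if candidate is None:
            candidate = _local_improving_mutant(theta, T, eq, params, scan)
        if candidate is None:
            break
        if previous is not None and abs(candidate - previous) < 1e-15:
            break  # two-cycle: neutrally flat landscape
        previous, theta = theta, candidate
    else:
        raise RuntimeError(
            f"trait substitution did not converge after {MAX_SUBSTITUTIONS} "
            f"steps (T={T}, start={theta_init})")

    return _polish_interior(theta, T, params, step)


def _polish_interior(theta: float, T: float, params: ModelParams,
                     step: float) -> float:
    """Snap an interior substitution endpoint onto the gradient zero."""
    if theta in (0.0, 1.0):
        return theta
    lo = max(GRADIENT_STEP, theta - 2 * step)
    hi = min(1.0 - GRADIENT_STEP, theta + 2 * step)
    try:
        g_lo = selection_gradient(lo, T, params)
        g_hi = selection_gradient(hi, T, params)
    except NonviableResidentError:
        return theta
    if g_lo == 0.0 or g_hi == 0.0 or np.sign(g_lo) == np.sign(g_hi):
        return theta
    return brentq(lambda th: selection_gradient(th, T, params), lo, hi,
                  xtol=1e-10)


def ess_curve(T_grid, params: ModelParams,
              theta_inits=None) -> list[ESSCurvePoint]:
    """Continue the substitution-sequence attractors along a temperature grid.

    Each branch is warm-started from its attractor at the previous
    temperature, preserving branch identity.  For concave (specialist)
    trade-offs two branches are run by default, from near-photoautotrophic
    and near-phagotrophic initial strategies, to expose the bistability
    created by the interior repeller.
    """
    T_grid = list(T_grid)
    if any(b < a for a, b in zip(T_grid, T_grid[1:])):
        raise ValueError("T_grid must be ascending")
    if theta_inits is None:
        theta_inits = (0.05, 0.95) if params.z < 0 else (0.0,)
    branches = list(theta_inits)

    points = []
    for T in T_grid:
        attractors = []
        viable_flags = []
        for bi, start in enumerate(branches):
            theta_end = ess_attractor(T, params, start)
            branches[bi] = theta_end
            attractors.append(theta_end)
            viable_flags.append(
                empty_environment_growth(theta_end, T, params) > 0.0)
        points.append(ESSCurvePoint(T=T, attractors=tuple(attractors),
                                    viable=tuple(viable_flags)))
    return points
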