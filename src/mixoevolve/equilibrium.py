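"""Resident ecological equilibria (M*, B*) for a fixed strategy and temperature.

The coupled mixotroph–bacteria system has no closed-form steady state, but at
any candidate mixotroph density ``M`` the bacterial quasi-equilibrium is the
prey nullcline ``B(M) = max(0, K_B·(1 − alpha·M/r))``.  Substituting it into
the mixotroph per-capita growth reduces the steady-state problem to a single
scalar root find in ``M``.  Because self-shading makes photosynthetic growth
strictly decreasing in ``M`` and grazing declines as prey are depleted, the
reduced growth function is monotone decreasing, so the interior root, when it
exists, is unique; a log-grid sign scan with Brent refinement is used anyway
as a robustness harness and any additional roots would be reported.

A strategy whose per-capita growth is non-positive even in an empty
environment (``M→0``, ``B=K_B``) cannot maintain a population; its state is
clipped to the empty boundary (M*=0, B*=K_B).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (EnvState, ModelParams, depth_avg_photo_growth,
                    grazing_growth, bacteria_rhs, mixotroph_rhs,
                    thermal_attack_rate)

__all__ = [
    "EquilibriumResult",
    "prey_nullcline",
    "empty_environment_growth",
    "find_resident_equilibrium",
    "local_stability",
]

log = logging.getLogger(__name__)

# log-spaced scan grid for the reduced 1-D root search (cells cm⁻²)
_M_SCAN_LO = 1e3
_M_SCAN_HI = 1e10
_M_SCAN_N = 200
_ROOT_RTOL = 1e-12


@dataclass(frozen=True)
class EquilibriumResult:
    """Resident steady state for one (theta, T).

    ``boundary`` is ``"interior"`` for a positive coexistence state,
    ``"empty"`` for the clipped M*=0, B*=K_B state, and ``"prey_extinct"``
    when grazing pressure at the root exceeds prey growth (alpha·M* ≥ r).
    ``residual`` is the largest absolute right-hand side at the reported
    state; ``roots`` lists every positive root found (normally one).
    """

    theta: float
    T: float
    M_star: float
    B_star: float
    viable: bool
    boundary: str
    residual: float
    locally_stable: bool
    roots: tuple = ()


def prey_nullcline(M: float, theta: float, T: float, params: ModelParams) -> float:
    """Non-negative prey density solving dB/dt = 0 at fixed mixotroph density."""
    if M < 0:
        raise ValueError(f"mixotroph density must be non-negative, got {M!r}")
    alpha = thermal_attack_rate(theta, T, params)
    return max(0.0, params.K_B * (1.0 - alpha * M / params.r))


def empty_environment_growth(theta: float, T: float, params: ModelParams) -> float:
    """Per-capita growth of a vanishingly rare mixotroph in an ungrazed system.

    Evaluated at ``M→0`` and ``B=K_B``; its sign decides viability (and the
    gray regions of pairwise invasibility plots).
    """
    return (depth_avg_photo_growth(theta, T, 0.0, params)
            + grazing_growth(theta, T, params.K_B, params)
            - params.l)


def _reduced_growth(M: float, theta: float, T: float, params: ModelParams) -> float:
    """Mixotroph per-capita growth with prey slaved to their nullcline."""
    B = prey_nullcline(M, theta, T, params)
    return (depth_avg_photo_growth(theta, T, M, params)
            + grazing_growth(theta, T, B, params)
            - params.l)


def find_resident_equilibrium(theta: float, T: float,
                              params: ModelParams) -> EquilibriumResult:
    """Solve the resident steady state, clipping non-viable strategies to M*=0."""
    g0 = empty_environment_growth(theta, T, params)
    if g0 <= 0.0:
        # Empty state is uninvadable by the resident itself: locally stable.
        return EquilibriumResult(theta=theta, T=T, M_star=0.0, B_star=params.K_B,
                                 viable=False, boundary="empty", residual=0.0,
                                 locally_stable=g0 < 0.0)

    grid = np.geomspace(_M_SCAN_LO, _M_SCAN_HI, _M_SCAN_N)
    f = lambda M: _reduced_growth(M, theta, T, params)
    values = np.array([f(M) for M in grid])

    roots = []
    # growth is positive at M→0; bracket every sign change on the scan grid
    prev_M, prev_v = 0.0, g0
    for M, v in zip(grid, values):
        if prev_v > 0.0 >= v:
            roots.append(brentq(f, max(prev_M, _M_SCAN_LO * 1e-6), M,
                                rtol=_ROOT_RTOL, maxiter=200))
        prev_M, prev_v = M, v
    if not roots:
        if values[-1] > 0.0:
            raise RuntimeError(
                "root bracketing failed: per-capita growth still positive at "
                f"M={_M_SCAN_HI:g} cells/cm^2 for theta={theta}, T={T}; "
                f"scanned [{_M_SCAN_LO:g}, {_M_SCAN_HI:g}]")
        raise RuntimeError(  # pragma: no cover - defensive
            f"no sign change found on [{_M_SCAN_LO:g}, {_M_SCAN_HI:g}] "
            f"for theta={theta}, T={T}")

    # monotone growth ⇒ unique root; keep the largest as the resident state
    M_star = max(roots)
    B_star = prey_nullcline(M_star, theta, T, params)
    boundary = "interior"
    if B_star == 0.0:
        boundary = "prey_extinct"
        log.warning("prey driven extinct at theta=%g, T=%g (alpha*M >= r); "
                    "outside the analyzed coexistence regime", theta, T)

    state = EnvState(M=M_star, B=B_star, T=T)
    residual = max(abs(mixotroph_rhs(state, theta, params)),
                   abs(bacteria_rhs(state, theta, params)))
    result = EquilibriumResult(theta=theta, T=T, M_star=M_star, B_star=B_star,
                               viable=True, boundary=boundary, residual=residual,
                               locally_stable=False, roots=tuple(roots))
    return dataclasses.replace(result, locally_stable=local_stability(result, params))


def local_stability(eq: EquilibriumResult, params: ModelParams) -> bool:
    """True iff the 2×2 Jacobian at (M*, B*) has eigenvalues with Re < 0.

    Finite-difference Jacobian of the full two-dimensional dynamics; the
    relative step is scaled to each density.
    """
    M0, B0, T = eq.M_star, eq.B_star, eq.T

    def rhs(M, B):
        state = EnvState(M=max(M, 0.0), B=max(B, 0.0), T=T)
        return np.array([mixotroph_rhs(state, eq.theta, params),
                         bacteria_rhs(state, eq.theta, params)])

    J = np.empty((2, 2))
    for j, (x0, setter) in enumerate([(M0, lambda x: (x, B0)),
                                      (B0, lambda x: (M0, x))]):
        dx = max(abs(x0), 1.0) * 1e-6
        J[:, j] = (rhs(*setter(x0 + dx)) - rhs(*setter(x0 - dx))) / (2.0 * dx)
    eigenvalues = np.linalg.eigvals(J)
    return bool(np.all(eigenvalues.real < 0.0))


def integrate_to_steady_state(theta: float, T: float, params: ModelParams,
                              M0: float | None = None, B0: float | None = None,
                              t_max: float = 5e4):
    """Forward-integrate the full dynamics as an independent equilibrium oracle.

    Returns the final ``(M, B)``.  Starts from a moderately dense mixotroph
    inoculum in an ungrazed bacterial community unless told otherwise.
    """
    from scipy.integrate import solve_ivp
    from .model import ode_rhs

    y0 = [M0 if M0 is not None else 1e4,
          B0 if B0 is not None else params.K_B]
    sol = solve_ivp(ode_rhs, (0.0, t_max), y0, args=(theta, T, params),
                    method="LSODA", rtol=1e-10, atol=1e-4)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return float(sol.y[0, -1]), float(sol.y[1, -1])
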