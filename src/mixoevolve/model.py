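"""Core mixotroph–bacteria model: parameters, per-capita rates, ODE right-hand sides.

The model describes a constitutive mixotroph population ``M`` (cells cm⁻²,
depth-integrated over a well-mixed water column) that grows by photosynthesis
and by phagotrophy on a logistically growing bacterial prey population ``B``
(cells cm⁻²).  A single evolving trait, the phagotrophic investment
``theta`` ∈ [0, 1], sets the split between the two metabolisms through a
trade-off curve whose curvature is controlled by the shape parameter ``z``
(convex ``z>0`` "generalist", linear ``z=0``, concave ``z<0`` "specialist").
Both metabolic rates scale with temperature, phagotrophy more steeply than
photosynthesis.

All per-capita rates are in d⁻¹; light levels are in µmol quanta m⁻² s⁻¹ and
the per-cell absorbance in cm² cell⁻¹, used at face value with no unit
conversion (the parameter set is internally consistent only if taken as
printed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ModelParams",
    "EnvState",
    "REFERENCE_T",
    "light_response",
    "tradeoff_rho0",
    "thermal_attack_rate",
    "thermal_photo_rate",
    "depth_avg_photo_growth",
    "grazing_growth",
    "mixotroph_rhs",
    "bacteria_rhs",
    "ode_rhs",
]

#: Temperature (°C) at which both thermal multipliers equal one with the
#: default coefficients, and the anchor of the exponential thermal variant.
REFERENCE_T = 13.0

# k·M below this is treated as optically thin and the analytic M→0 limit of
# the depth-averaged light factor is used (removable singularity).
_THIN_LAYER_KM = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """Model constants.

    ``z`` has no default: the trade-off shape is the single most consequential
    choice and must be stated explicitly.  Every other field defaults to the
    standard parameterization for marine *Ochromonas*-like mixotrophs.

    Parameters
    ----------
    z : float
        Trade-off shape; the canonical cases are −1 (specialist), 0 (linear)
        and 1 (generalist).
    rho_max : float
        Maximum carbon-uptake (photosynthesis) rate, d⁻¹.
    alpha_max : float
        Maximum attack rate on bacteria, cm² d⁻¹ cell_M⁻¹.
    b : float
        Conversion of captured bacteria into mixotroph cells, cell_M cell_B⁻¹.
    K_B : float
        Bacterial carrying capacity, cell_B cm⁻².
    r : float
        Bacterial growth rate, d⁻¹ (held temperature-independent).
    h : float
        Half-saturation light level for photosynthesis, µmol quanta m⁻² s⁻¹.
    I_in : float
        Incident (surface) light, same units as ``h``.
    k : float
        Per-cell light absorbance, cm² cell_M⁻¹.
    l : float
        Mixotroph mortality, d⁻¹.
    m_rho, m_alpha : float
        Linear thermal sensitivities of photosynthesis and phagotrophy, °C⁻¹.
    T0_rho, T0_alpha : float
        Temperatures (°C) at which photosynthesis / phagotrophy reach zero.
    thermal_response : str
        ``"linear"`` (default): multiplier ``max(0, m·(T−T0))``;
        ``"exponential"``: multiplier ``exp(m·(T−13))``, normalized to one at
        13 °C, as a sensitivity variant.
    """

    z: float
    rho_max: float = 1.0
    alpha_max: float = 0.15e-8
    b: float = 0.15
    K_B: float = 1e8
    r: float = 0.693
    h: float = 250.0
    I_in: float = 100.0
    k: float = 5e-7
    l: float = 0.05
    m_rho: float = 0.1
    m_alpha: float = 0.25
    T0_rho: float = 3.0
    T0_alpha: float = 9.0
    thermal_response: str = "linear"

    def __post_init__(self) -> None:
        positive = ("rho_max", "alpha_max", "b", "K_B", "r", "h", "I_in", "k",
                    "m_rho", "m_alpha")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, "
                                 f"got {getattr(self, name)!r}")
        if self.l < 0:
            raise ValueError(f"mortality l must be >= 0, got {self.l!r}")
        if self.thermal_response not in ("linear", "exponential"):
            raise ValueError("thermal_response must be 'linear' or 'exponential', "
                             f"got {self.thermal_response!r}")

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class EnvState:
    """Instantaneous environmental state: densities and temperature."""

    M: float  # mixotrophs, cell_M cm⁻²
    B: float  # bacterial prey, cell_B cm⁻²
    T: float  # temperature, °C

    def __post_init__(self) -> None:
        if self.M < 0 or self.B < 0:
            raise ValueError(f"densities must be non-negative, got M={self.M}, B={self.B}")


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"phagotrophic investment theta must lie in [0, 1], got {theta!r}")


def light_response(I: float, params: ModelParams) -> float:
    """Saturating (Monod) photosynthetic rate at irradiance ``I``, d⁻¹."""
    if I < 0:
        raise ValueError(f"irradiance must be non-negative, got {I!r}")
    return params.rho_max * I / (params.h + I)


def tradeoff_rho0(theta: float, params: ModelParams) -> float:
    """Maximum photosynthetic rate under the investment trade-off, d⁻¹.

    ``rho0(theta) = rho_max · (1 − theta^(2^z))^(2^(−z))`` — decreasing from
    ``rho_max`` at full photosynthesis (theta=0) to zero at full phagotrophy
    (theta=1).  ``z>0`` bows the curve outward (a generalist keeps most of
    both metabolisms), ``z<0`` inward (any mixed strategy is penalized).
    """
    _check_theta(theta)
    a = 2.0 ** params.z
    return params.rho_max * (1.0 - theta ** a) ** (1.0 / a)


def _thermal_multiplier(T: float, m: float, T0: float, params: ModelParams) -> float:
    if params.thermal_response == "exponential":
        return math.exp(m * (T - REFERENCE_T))
    return max(0.0, m * (T - T0))


def thermal_attack_rate(theta: float, T: float, params: ModelParams) -> float:
    """Temperature-scaled attack rate ``alpha(theta, T)``, cm² d⁻¹ cell_M⁻¹.

    Zero below ``T0_alpha`` (linear response) and proportional to the
    phagotrophic investment.
    """
    _check_theta(theta)
    return params.alpha_max * theta * _thermal_multiplier(T, params.m_alpha,
                                                          params.T0_alpha, params)


def thermal_photo_rate(theta: float, T: float, params: ModelParams) -> float:
    """Temperature-scaled maximum photosynthetic rate ``rho(theta, z, T)``, d⁻¹."""
    return tradeoff_rho0(theta, params) * _thermal_multiplier(
        T, params.m_rho, params.T0_rho, params)


def _depth_avg_light_factor(M: float, params: ModelParams) -> float:
    """Depth-averaged fraction ``(1/kM)·ln((h+I_in)/(h+I_in·e^{−kM}))``.

    Light attenuates with depth through self-shading by the ``M`` cells above;
    averaging the saturating light response over the water column gives this
    factor (dimensionless, in (0, I_in/(h+I_in)]).  The apparent 0/0 at M=0 is
    removable: the limit is the surface value ``I_in/(h+I_in)``.
    """
    if M < 0:
        raise ValueError(f"mixotroph density must be non-negative, got {M!r}")
    kM = params.k * M
    if kM < _THIN_LAYER_KM:
        return params.I_in / (params.h + params.I_in)
    return math.log((params.h + params.I_in)
                    / (params.h + params.I_in * math.exp(-kM))) / kM


def depth_avg_photo_growth(theta: float, T: float, M: float,
                           params: ModelParams) -> float:
    """Per-capita photosynthetic growth ``P(theta, z, I_in, T, M)``, d⁻¹.

    Strictly decreasing in ``M`` (self-shading); continuous at ``M=0`` with
    value ``rho(theta,z,T)·I_in/(h+I_in)``.
    """
    rho = thermal_photo_rate(theta, T, params)
    if rho == 0.0:
        # still validates M
        _depth_avg_light_factor(M, params)
        return 0.0
    return rho * _depth_avg_light_factor(M, params)


def grazing_growth(theta: float, T: float, B: float, params: ModelParams) -> float:
    """Per-capita phagotrophic growth ``G(theta, T, B) = b·alpha·B``, d⁻¹ (Type I)."""
    if B < 0:
        raise ValueError(f"prey density must be non-negative, got {B!r}")
    return params.b * thermal_attack_rate(theta, T, params) * B


def mixotroph_rhs(state: EnvState, theta: float, params: ModelParams) -> float:
    """dM/dt = [P + G − l]·M, cell_M cm⁻² d⁻¹."""
    per_capita = (depth_avg_photo_growth(theta, state.T, state.M, params)
                  + grazing_growth(theta, state.T, state.B, params)
                  - params.l)
    return per_capita * state.M


def bacteria_rhs(state: EnvState, theta: float, params: ModelParams) -> float:
    """dB/dt = [r(1 − B/K_B) − alpha·M]·B, cell_B cm⁻² d⁻¹."""
    per_capita = (params.r * (1.0 - state.B / params.K_B)
                  - thermal_attack_rate(theta, state.T, params) * state.M)
    return per_capita * state.B


def ode_rhs(t: float, y, theta: float, T: float, params: ModelParams):
    """Right-hand side ``f(t, [M, B])`` for scipy ODE solvers.

    Densities are clipped at zero before evaluation so that integrators may
    overshoot slightly without tripping validation.
    """
    state = EnvState(M=max(0.0, float(y[0])), B=max(0.0, float(y[1])), T=T)
    return [mixotroph_rhs(state, theta, params),
            bacteria_rhs(state, theta, params)]
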