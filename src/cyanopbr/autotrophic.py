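"""Photo-autotrophic growth and maximum sustainable biomass density.

Under nitrogen and CO2 sufficiency the biomass balance is logistic-like:
light-limited growth against quadratic decay,

    dX/dt = kbar(I; X) * mu_max_a * X - mu_d_a * X**2,

where kbar is the depth-averaged Aiba response, itself a decreasing
function of X through self-shading.  The batch plateau ("Cmax") is the
nontrivial equilibrium kbar(I; X) * mu_max_a = mu_d_a * X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .light import (
    GROWTH_RESPONSE,
    LightConfig,
    OpticalParams,
    PhotoResponseParams,
    depth_averaged_response,
)
from .state import Trajectory

__all__ = [
    "AutotrophicParams",
    "rhs_autotrophic",
    "simulate_autotrophic",
    "steady_state_cmax",
]


@dataclass(frozen=True)
class AutotrophicParams:
    """Kinetic constants of photo-autotrophic growth.

    mu_max_a : maximum specific growth rate, h^-1 (default 0.255)
    mu_d_a   : decay coefficient, L h^-1 g^-1 (default 0.00227)
    growth_response : Aiba constants ks=165, ki=457 µmol m^-2 s^-1
    """

    mu_max_a: float = 0.255
    mu_d_a: float = 0.00227
    growth_response: PhotoResponseParams = field(default_factory=lambda: GROWTH_RESPONSE)

    def __post_init__(self) -> None:
        if self.mu_max_a <= 0 or self.mu_d_a <= 0:
            raise ValueError("autotrophic rate constants must be strictly positive")


def rhs_autotrophic(
    X: float,
    params: AutotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
) -> float:
    """Biomass growth rate dX/dt in g L^-1 h^-1 at concentration ``X``."""
    if X < 0:
        raise ValueError("biomass concentration must be non-negative")
    kbar = depth_averaged_response(X, optics, light, params.growth_response)
    return kbar * params.mu_max_a * X - params.mu_d_a * X**2


def simulate_autotrophic(
    X0: float,
    t_grid: np.ndarray,
    params: AutotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the batch growth curve on the requested time grid (h)."""
    if X0 <= 0:
        raise ValueError("X0 must be strictly positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with at least two points")

    sol = solve_ivp(
        lambda t, y: [rhs_autotrophic(max(y[0], 0.0), params, optics, light)],
        (t_grid[0], t_grid[-1]),
        [X0],
        method="BDF",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"autotrophic integration failed: {sol.message}")
    return Trajectory(sol.t, {"X": sol.y[0]})


def steady_state_cmax(
    params: AutotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    bracket: tuple[float, float] = (1e-3, 1e3),
    rtol: float = 1e-6,
) -> float:
    """Maximum sustainable biomass concentration Cmax, g L^-1.

    The positive root of ``kbar(I; X) * mu_max_a = mu_d_a * X``, located
    by bisection on a bracket spanning all physically plausible
    densities.  Equals the long-time plateau of the batch simulation.
    """
    lo, hi = bracket

    def balance(X: float) -> float:
        kbar = depth_averaged_response(X, optics, light, params.growth_response)
        return kbar * params.mu_max_a - params.mu_d_a * X

    f_lo, f_hi = balance(lo), balance(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of the growth-decay balance on [{lo}, {hi}] g/L "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    return float(brentq(balance, lo, hi, rtol=rtol))
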