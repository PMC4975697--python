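"""Photo-heterotrophic growth and biohydrogen production dynamics.

Six coupled stiff ODEs describe a batch culture growing on glycerol
under nitrate limitation: biomass X, extracellular nitrate N, normalized
intracellular nitrogen quota q (Droop kinetics — growth runs on the
internal pool and stops as q falls to the minimum quota kq), glycerol C,
oxygen O2 and cumulative hydrogen H2.  Hydrogen is made by nitrogenase,
which is active only in a near-anaerobic, nitrate-depleted culture; two
smooth switch functions gate the production term accordingly:

    dX/dt  = kbar*mu_max_h*(1 - kq/q)*X*C/(C+KC) - mu_d_h*X**2
    dN/dt  = -Y_NX*kbar*mu_max_h*N/(N+KN)*X
    dq/dt  = Y_qX*kbar*mu_max_h*N/(N+KN) - kbar*mu_max_h*(1 - kq/q)*q*C/(C+KC)
    dH2/dt = Y_HX*hbar*X*fN(N)*fO(O2)
    dO2/dt = Y_OX*kbar*mu_max_h*N/(N+KN)*X - Y_Od*mu_d_h*X**2*(1 - fO(O2))
    dC/dt  = -Y_CX*(growth) - Y_C*X

with kbar, hbar the depth-averaged light responses of growth and of
hydrogen production.  The system is integrated with an implicit
stiff-capable method; an explicit fixed-step RK4 integrator is provided
as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .light import (
    GROWTH_RESPONSE,
    H2_RESPONSE,
    LightConfig,
    OpticalParams,
    PhotoResponseParams,
    _depth_averages,
)
from .state import STATE_VARS, CultureState, Trajectory

__all__ = [
    "HeterotrophicParams",
    "switch_fN",
    "switch_fO",
    "rhs_heterotrophic",
    "simulate_heterotrophic",
    "simulate_heterotrophic_rk4",
    "average_h2_productivity",
    "stationary_phase_state",
]


@dataclass(frozen=True)
class HeterotrophicParams:
    """Kinetic constants and yields of the hydrogen-production model.

    Defaults are the fitted laboratory values.  ``growth_response`` is
    shared with the autotrophic model (the Aiba constants of growth are
    independent of cultivation mode); ``h2_response`` is the separate
    light response of nitrogenase-mediated H2 production.
    """

    mu_max_h: float = 0.332     # h^-1
    mu_d_h: float = 0.00716     # L h^-1 g^-1
    kq: float = 0.165           # - (normalized minimum nitrogen quota)
    KN: float = 50.0            # mg L^-1
    KC: float = 0.0             # mmol L^-1
    Y_NX: float = 492.7         # mg g^-1
    Y_qX: float = 0.0317        # g^-1
    Y_HX: float = 14.20         # mL g^-1 h^-1
    Y_OX: float = 81.02         # L g^-1
    Y_Od: float = 486.03        # L g^-2
    Y_CX: float = 20.454        # mmol g^-1
    Y_C: float = 0.0301         # mmol g^-1 h^-1
    h2_response: PhotoResponseParams = field(default_factory=lambda: H2_RESPONSE)
    growth_response: PhotoResponseParams = field(default_factory=lambda: GROWTH_RESPONSE)

    def __post_init__(self) -> None:
        for name in (
            "mu_max_h", "mu_d_h", "kq", "KN", "KC", "Y_NX", "Y_qX",
            "Y_HX", "Y_OX", "Y_Od", "Y_CX", "Y_C",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"HeterotrophicParams.{name} must be non-negative")
        if not 0 < self.kq <= 1:
            raise ValueError("kq must lie in (0, 1]")


def switch_fN(N):
    """Nitrate switch: 1 in a nitrate-depleted culture, exactly 0 for N >= 100 mg/L.

    ``0.5*(sqrt((N-100)^2) - (N-100)) / sqrt((N-100)^2 + 0.1)`` — a
    smooth ramp whose numerator vanishes identically above the
    100 mg L^-1 nitrogenase-inhibition threshold.
    """
    N = np.asarray(N, dtype=float)
    d = N - 100.0
    out = 0.5 * (np.abs(d) - d) / np.sqrt(d**2 + 0.1)
    return float(out) if out.ndim == 0 else out


def switch_fO(O2):
    """Oxygen switch: 1 when anaerobic, -> 0 as O2 accumulates.

    ``1 - O2/sqrt(O2^2 + 0.1)`` in the model's oxygen units (L L^-1).
    """
    O2 = np.asarray(O2, dtype=float)
    out = 1.0 - O2 / np.sqrt(O2**2 + 0.1)
    return float(out) if out.ndim == 0 else out


def _rhs(y, params: HeterotrophicParams, optics: OpticalParams, light: LightConfig):
    """Raw derivative vector for an array state (X, N, q, C, O2, H2).

    States are not clamped; the light field sees max(X, 0) so that the
    tiny negative excursions a stiff solver may probe stay harmless.
    """
    X, N, q, C, O2, _H2 = y
    kbar, hbar = _depth_averages(
        max(X, 0.0), optics, light, (params.growth_response, params.h2_response)
    )

    # Monod factors; KC = 0 degenerates to a glycerol on/off indicator.
    monod_N = N / (N + params.KN)
    if params.KC > 0:
        monod_C = max(C, 0.0) / (max(C, 0.0) + params.KC)
    else:
        monod_C = 1.0 if C > 0 else 0.0

    quota_factor = 1.0 - params.kq / q
    uptake = kbar * params.mu_max_h * monod_N          # per-quota nitrate uptake drive
    growth = kbar * params.mu_max_h * quota_factor * X * monod_C
    decay = params.mu_d_h * X**2
    fN = switch_fN(N)
    fO = switch_fO(O2)

    dX = growth - decay
    dN = -params.Y_NX * uptake * X
    dq = params.Y_qX * uptake - kbar * params.mu_max_h * quota_factor * q * monod_C
    dC = -params.Y_CX * growth - params.Y_C * X * (1.0 if C > 0 else 0.0)
    dO2 = params.Y_OX * uptake * X - params.Y_Od * decay * (1.0 - fO)
    dH2 = params.Y_HX * hbar * X * fN * fO
    return np.array([dX, dN, dq, dC, dO2, dH2])


def rhs_heterotrophic(
    state: CultureState,
    params: HeterotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
) -> dict[str, float]:
    """Time derivatives of all six state variables, keyed by name."""
    dy = _rhs(state.as_array(), params, optics, light)
    return dict(zip(STATE_VARS, map(float, dy)))


def simulate_heterotrophic(
    state0: CultureState,
    t_grid: np.ndarray,
    params: HeterotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the batch with a stiff implicit solver.

    Parameters
    ----------
    t_grid : array
        Strictly increasing output times, h.
    method : str
        Any implicit ``solve_ivp`` method ("BDF", "Radau", "LSODA").

    Returns
    -------
    Trajectory with columns t, X, N, q, C, O2, H2.  Negative-state
    excursions beyond ``atol`` raise, as they indicate solver
    misconfiguration rather than model behaviour.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with at least two points")

    sol = solve_ivp(
        lambda t, y: _rhs(y, params, optics, light),
        (t_grid[0], t_grid[-1]),
        state0.as_array(),
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"heterotrophic integration failed: {sol.message}")
    y = sol.y
    excursion = float(np.minimum(y, 0.0).min())
    if excursion < -100 * max(atol, 1e-12):
        raise RuntimeError(
            f"state excursion {excursion:.3g} below zero exceeds tolerance; "
            "tighten rtol/atol or inspect the configuration"
        )
    return Trajectory(sol.t, dict(zip(STATE_VARS, y)))


def simulate_heterotrophic_rk4(
    state0: CultureState,
    t_grid: np.ndarray,
    params: HeterotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    dt: float = 1e-3,
) -> Trajectory:
    """Explicit fixed-step RK4 reference integrator.

    Slow and non-stiff-safe by construction; kept as an independent
    cross-check of the implicit solver, not for production runs.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty((t_grid.size, 6))
    y = state0.as_array()
    t = t_grid[0]
    out[0] = y
    for k in range(1, t_grid.size):
        t_target = t_grid[k]
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            k1 = _rhs(y, params, optics, light)
            k2 = _rhs(y + 0.5 * h * k1, params, optics, light)
            k3 = _rhs(y + 0.5 * h * k2, params, optics, light)
            k4 = _rhs(y + h * k3, params, optics, light)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[k] = y
    return Trajectory(t_grid, dict(zip(STATE_VARS, out.T)))


def stationary_phase_state(X0: float = 3.5, C0: float = 50.0) -> CultureState:
    """Scale-up preset: a nitrate-exhausted culture entering H2 production.

    Hydrogen is made mainly in the stationary and decay phases, so the
    sweep starts with nitrate gone, quota at its minimum and an
    anaerobic culture: N=0, q=kq, O2=0, glycerol still ample.
    """
    return CultureState(X=X0, N=0.0, q=HeterotrophicParams().kq, C=C0, O2=0.0, H2=0.0)


def average_h2_productivity(
    state0: CultureState,
    duration_h: float,
    params: HeterotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    n_points: int = 241,
    **solver_kwargs,
) -> float:
    """Mean hydrogen production rate H2(T)/T over a batch, mL L^-1 h^-1."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    t_grid = np.linspace(0.0, duration_h, n_points)
    traj = simulate_heterotrophic(state0, t_grid, params, optics, light, **solver_kwargs)
    return float(traj["H2"][-1] / duration_h)
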