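"""Sensitivity analysis, reactor scale-up sweeps and the low-chlorophyll mutant.

Three post-hoc analyses of the kinetic models:

* local normalized sensitivity S_y/x = (dy/dx)*(x/y) of any simulated
  output with respect to any kinetic parameter, by central finite
  differences;
* a scale-up sweep predicting either the maximum photo-autotrophic
  biomass density (Cmax) or the 240 h average hydrogen productivity for
  a list of reactor configurations (incident intensity, number of lit
  faces, width);
* a parameter transform describing a hypothetical low-chlorophyll
  mutant whose photosystem cross-section is reduced by a fraction r:
  the Aiba constants scale as 1/(1-r) and the cellular extinction
  cross-section as (1-r), so the mutant absorbs less and self-shades
  less.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autotrophic import AutotrophicParams, steady_state_cmax
from .heterotrophic import (
    HeterotrophicParams,
    average_h2_productivity,
    simulate_heterotrophic,
)
from .light import LightConfig, OpticalParams, PhotoResponseParams
from .state import CultureState

__all__ = [
    "SensitivityResult",
    "ReactorSpec",
    "MutantScenario",
    "normalized_sensitivity",
    "scaleup_sweep",
    "mutant_transform",
]


@dataclass
class SensitivityResult:
    """Normalized sensitivity of one output to one parameter over time.

    ``S`` is zero (and ``defined`` False) wherever |output| falls below
    the floor, since the normalization is singular there.
    """

    output: str
    parameter: str
    times: np.ndarray
    S: np.ndarray
    defined: np.ndarray

    def max_abs(self) -> float:
        """Largest |S| over the window where the output is defined."""
        if not self.defined.any():
            raise ValueError(
                f"output {self.output!r} never exceeds the floor; "
                "sensitivity undefined over the whole window"
            )
        return float(np.max(np.abs(self.S[self.defined])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "output": self.output,
                "parameter": self.parameter,
                "S": self.S,
                "defined": self.defined,
            }
        )


def normalized_sensitivity(
    output: str,
    parameter: str,
    state0: CultureState,
    params: HeterotrophicParams,
    optics: OpticalParams,
    light: LightConfig,
    t_grid: np.ndarray,
    rel_step: float = 0.01,
    floor: float = 1e-6,
) -> SensitivityResult:
    """Central-difference normalized sensitivity of a batch output.

    S(t) = [y(x(1+d), t) - y(x(1-d), t)] / (2 d y(x, t)), the
    dimensionless percent-per-percent influence of parameter ``x`` on
    output ``y``.  A positive value means increasing the parameter
    raises the output.

    Parameters
    ----------
    rel_step : float
        Relative perturbation d (default 1%).
    floor : float
        |y| threshold below which S is reported undefined (output
        units).
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    x = getattr(params, parameter)
    if not isinstance(x, (int, float)):
        raise ValueError(f"parameter {parameter!r} is not a scalar kinetic constant")
    if x == 0:
        raise ValueError(f"parameter {parameter!r} is zero; normalized sensitivity undefined")
    t_grid = np.asarray(t_grid, dtype=float)
    # state0 is the culture at t=0; integrate from there even when the
    # requested grid starts later.
    prepend = t_grid[0] > 0
    t_sim = np.concatenate([[0.0], t_grid]) if prepend else t_grid

    def run(scale: float) -> np.ndarray:
        p = dataclasses.replace(params, **{parameter: x * scale})
        y = simulate_heterotrophic(state0, t_sim, p, optics, light)[output]
        return y[1:] if prepend else y

    y0 = run(1.0)
    y_hi = run(1.0 + rel_step)
    y_lo = run(1.0 - rel_step)

    defined = np.abs(y0) > floor
    S = np.zeros_like(y0)
    S[defined] = (y_hi[defined] - y_lo[defined]) / (2.0 * rel_step * y0[defined])
    return SensitivityResult(output, parameter, t_grid, S, defined)


@dataclass(frozen=True)
class ReactorSpec:
    """One flat-plate configuration: intensity per face, faces, width."""

    I0: float
    n_surfaces: int
    d: float

    def key(self) -> str:
        d = f"{self.d:g}"
        return f"{self.I0:g}-{self.n_surfaces}-{d}"


#: Reactor configurations of the published Cmax comparison.
CMAX_SPECS = (
    ReactorSpec(457, 1, 0.025), ReactorSpec(457, 1, 0.10),
    ReactorSpec(457, 1, 0.20), ReactorSpec(457, 1, 0.50),
    ReactorSpec(114, 2, 0.20), ReactorSpec(229, 2, 0.20),
    ReactorSpec(457, 2, 0.20), ReactorSpec(914, 2, 0.20),
)

#: Reactor configurations of the published H2-productivity comparison.
H2_SPECS = (
    ReactorSpec(457, 1, 0.025), ReactorSpec(457, 1, 0.05),
    ReactorSpec(457, 1, 0.1), ReactorSpec(457, 1, 0.2),
    ReactorSpec(114, 2, 0.20), ReactorSpec(229, 2, 0.20),
    ReactorSpec(457, 2, 0.20), ReactorSpec(914, 2, 0.20),
)


def scaleup_sweep(
    specs: list[ReactorSpec],
    mode: str,
    auto_params: AutotrophicParams | None = None,
    het_params: HeterotrophicParams | None = None,
    optics: OpticalParams | None = None,
    X0: float = 3.5,
    C0: float = 50.0,
    duration_h: float = 240.0,
    n_steps: int = 2000,
) -> pd.DataFrame:
    """Predict Cmax or average H2 productivity across reactor designs.

    mode="cmax" assumes photo-autotrophic growth and returns the
    equilibrium biomass density; mode="h2" starts a nitrate-exhausted
    (stationary-phase) photo-heterotrophic culture at ``X0`` g/L and
    averages hydrogen over ``duration_h`` hours.

    The depth quadrature defaults to a high resolution (``n_steps``):
    wide reactors confine the photic zone to a few millimetres at the
    lit faces, which a 20-interval rule cannot resolve at d >= 0.1 m.

    Failures of individual configurations are isolated: the row is
    reported with value NaN and the error message, and the sweep
    continues.
    """
    if mode not in ("cmax", "h2"):
        raise ValueError("mode must be 'cmax' or 'h2'")
    auto_params = auto_params or AutotrophicParams()
    het_params = het_params or HeterotrophicParams()
    optics = optics or OpticalParams()

    rows = []
    for spec in specs:
        try:
            lc = LightConfig(I0=spec.I0, L=spec.d, n_surfaces=spec.n_surfaces, n_steps=n_steps)
            if mode == "cmax":
                value = steady_state_cmax(auto_params, optics, lc)
                metric = "Cmax (g L^-1)"
            else:
                state0 = CultureState(X=X0, N=0.0, q=het_params.kq, C=C0, O2=0.0)
                value = average_h2_productivity(state0, duration_h, het_params, optics, lc)
                metric = "H2 (mL L^-1 h^-1)"
            error = ""
        except Exception as exc:  # isolate per-spec failures
            value, error = float("nan"), str(exc)
            metric = "Cmax (g L^-1)" if mode == "cmax" else "H2 (mL L^-1 h^-1)"
        rows.append(
            {
                "I0": spec.I0,
                "n_surfaces": spec.n_surfaces,
                "d": spec.d,
                "metric": metric,
                "value": value,
                "error": error,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MutantScenario:
    """A low-chlorophyll mutant with photosystem cross-section reduced by ``r``."""

    cross_section_reduction: float = 0.30

    def __post_init__(self) -> None:
        r = self.cross_section_reduction
        if not 0 <= r < 1:
            raise ValueError("cross-section reduction must lie in [0, 1)")


def _scale_response(p: PhotoResponseParams, factor: float) -> PhotoResponseParams:
    return PhotoResponseParams(ks=p.ks / factor, ki=p.ki / factor)


def mutant_transform(params, optics: OpticalParams, scenario: MutantScenario):
    """Transform kinetic and optical parameters for the mutant strain.

    With the cross-section scaled to (1-r) of wild type, both Aiba
    constants scale as 1/(1-r) (they are inversely proportional to the
    cross-section) and the cellular extinction coefficient tau_c scales
    as (1-r) (proportional to the chlorophyll mass fraction).  All
    other kinetic constants are unchanged.

    Parameters
    ----------
    params : AutotrophicParams or HeterotrophicParams
    optics : OpticalParams

    Returns
    -------
    (params', optics') of the same types.
    """
    r = scenario.cross_section_reduction
    factor = 1.0 - r
    new_optics = dataclasses.replace(optics, tau_c=optics.tau_c * factor)
    if isinstance(params, AutotrophicParams):
        new_params = dataclasses.replace(
            params, growth_response=_scale_response(params.growth_response, factor)
        )
    elif isinstance(params, HeterotrophicParams):
        new_params = dataclasses.replace(
            params,
            growth_response=_scale_response(params.growth_response, factor),
            h2_response=_scale_response(params.h2_response, factor),
        )
    else:
        raise TypeError("params must be AutotrophicParams or HeterotrophicParams")
    return new_params, new_optics
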