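"""Light field in a flat-plate photobioreactor.

Irradiance entering through one or two faces of a flat plate decays
exponentially with depth (Beer–Lambert), with extinction contributed by
cell absorption and by scattering off the sparging bubbles.  The local
photosynthetic response follows the Aiba substrate-inhibition form

    k(I) = I / (I + ks + I**2 / ki),

which saturates at moderate irradiance and is inhibited at high
irradiance.  Growth and hydrogen production feel the *depth average* of
this response, evaluated with a composite trapezoid rule over the light
path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "OpticalParams",
    "LightConfig",
    "PhotoResponseParams",
    "GROWTH_RESPONSE",
    "H2_RESPONSE",
    "photoresponse",
    "optimal_intensity",
    "attenuation_coefficient",
    "local_intensity",
    "depth_averaged_response",
]


@dataclass(frozen=True)
class OpticalParams:
    """Optical properties of the culture.

    Attributes
    ----------
    tau_c : float
        Light absorption cross-section of the cells, m^2 g^-1.
    alpha_g : float
        Gas hold-up fraction of the sparged culture (dimensionless).
    d_b : float
        Mean bubble diameter, m.
    """

    tau_c: float = 0.126
    alpha_g: float = 0.0067
    d_b: float = 0.002

    def __post_init__(self) -> None:
        # tau_c/alpha_g may be zero: the transparent-medium limit is a
        # useful analytic reference.  Bubble diameter must stay positive.
        if self.tau_c < 0 or self.alpha_g < 0:
            raise ValueError("OpticalParams.tau_c and alpha_g must be non-negative")
        if self.d_b <= 0:
            raise ValueError("OpticalParams.d_b must be strictly positive")


@dataclass(frozen=True)
class LightConfig:
    """Geometry and illumination of the flat plate.

    Attributes
    ----------
    I0 : float
        Incident photon flux density per illuminated surface,
        µmol m^-2 s^-1.
    L : float
        Reactor width (light path), m.
    n_surfaces : int
        Number of illuminated faces, 1 or 2.  With two faces each
        contributes an independent exponential with intensity ``I0``.
    n_steps : int
        Number of equal depth intervals for the composite trapezoid
        average (default 20).
    """

    I0: float = 92.0
    L: float = 0.025
    n_surfaces: int = 1
    n_steps: int = 20

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("LightConfig.I0 must be non-negative")
        if self.L <= 0:
            raise ValueError("LightConfig.L must be strictly positive")
        if self.n_surfaces not in (1, 2):
            raise ValueError("LightConfig.n_surfaces must be 1 or 2")
        if self.n_steps < 2:
            raise ValueError("LightConfig.n_steps must be at least 2")


@dataclass(frozen=True)
class PhotoResponseParams:
    """Aiba light-response constants (both in µmol m^-2 s^-1)."""

    ks: float
    ki: float

    def __post_init__(self) -> None:
        if self.ks <= 0 or self.ki <= 0:
            raise ValueError("PhotoResponseParams constants must be strictly positive")


#: Light response of cell growth (shared by both cultivation modes).
GROWTH_RESPONSE = PhotoResponseParams(ks=165.0, ki=457.0)

#: Light response of nitrogenase-mediated hydrogen production.
H2_RESPONSE = PhotoResponseParams(ks=140.0, ki=457.0)


def photoresponse(I, p: PhotoResponseParams):
    """Aiba photoresponse factor ``I / (I + ks + I**2/ki)``.

    Dimensionless, in ``[0, 1)``; vanishes in the dark and under extreme
    photoinhibition, and peaks at ``I* = sqrt(ks*ki)``.

    Parameters
    ----------
    I : float or ndarray
        Local light intensity, µmol m^-2 s^-1.  Must be non-negative.
    p : PhotoResponseParams
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("light intensity must be non-negative")
    out = I / (I + p.ks + I**2 / p.ki)
    return float(out) if out.ndim == 0 else out


def optimal_intensity(p: PhotoResponseParams) -> float:
    """Intensity maximizing the Aiba response, ``sqrt(ks*ki)``."""
    return float(np.sqrt(p.ks * p.ki))


def attenuation_coefficient(X: float, optics: OpticalParams) -> float:
    """Extinction coefficient of the culture, m^-1.

    ``tau_c * (1000*X) + 3*alpha_g/d_b``: cell absorption (biomass
    converted from g L^-1 to g m^-3) plus bubble scattering.
    """
    if X < 0:
        raise ValueError("biomass concentration must be non-negative")
    return optics.tau_c * (1000.0 * X) + 3.0 * optics.alpha_g / optics.d_b


def local_intensity(z, X: float, optics: OpticalParams, lc: LightConfig):
    """Local light intensity at depth ``z`` from the front face.

    One-sided illumination gives ``I0*exp(-a*z)``; two-sided adds the
    mirrored exponential ``I0*exp(-a*(L-z))``.

    Parameters
    ----------
    z : float or ndarray
        Depth from the illuminated (front) face, m, in ``[0, L]``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > lc.L):
        raise ValueError(f"depth must lie in [0, {lc.L}] m")
    a = attenuation_coefficient(X, optics)
    I = lc.I0 * np.exp(-a * z)
    if lc.n_surfaces == 2:
        I = I + lc.I0 * np.exp(-a * (lc.L - z))
    return float(I) if I.ndim == 0 else I


def depth_averaged_response(
    X: float,
    optics: OpticalParams,
    lc: LightConfig,
    p: PhotoResponseParams,
    n_steps: int | None = None,
):
    """Depth-averaged photoresponse k̄ (or h̄) over the light path.

    Composite trapezoid rule on ``n_steps`` equal depth intervals:

        (1/(2n)) * (f(I(z0)) + 2*sum(f(I(zi))) + f(I(zn)))

    Parameters
    ----------
    n_steps : int, optional
        Override the interval count of ``lc`` (e.g. a large value as a
        high-resolution reference quadrature).
    """
    n = lc.n_steps if n_steps is None else int(n_steps)
    if n < 2:
        raise ValueError("n_steps must be at least 2")
    z = np.linspace(0.0, lc.L, n + 1)
    f = photoresponse(local_intensity(z, X, optics, lc), p)
    w = np.full(n + 1, 2.0)
    w[0] = w[-1] = 1.0
    return float((w * f).sum() / (2.0 * n))


@lru_cache(maxsize=64)
def _zgrid(L: float, n: int) -> np.ndarray:
    z = np.linspace(0.0, L, n + 1)
    z.setflags(write=False)
    return z


def _depth_averages(
    X: float,
    optics: OpticalParams,
    lc: LightConfig,
    responses: tuple[PhotoResponseParams, ...],
) -> tuple[float, ...]:
    """Depth averages of several responses sharing one intensity profile.

    Internal fast path for ODE right-hand sides; identical arithmetic to
    :func:`depth_averaged_response` but skips revalidation and reuses the
    attenuation profile across responses.
    """
    n = lc.n_steps
    z = _zgrid(lc.L, n)
    a = optics.tau_c * (1000.0 * X) + 3.0 * optics.alpha_g / optics.d_b
    I = lc.I0 * np.exp(-a * z)
    if lc.n_surfaces == 2:
        I = I + I[::-1]
    out = []
    for p in responses:
        f = I / (I + p.ks + I * I / p.ki)
        out.append((f.sum() - 0.5 * (f[0] + f[-1])) / n)
    return tuple(out)
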