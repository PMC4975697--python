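"""Run configuration: YAML parameter files with unit validation.

A configuration file is a hierarchical key-value (YAML) document whose
blocks mirror the model structure (optics, light, autotrophic,
heterotrophic, initial_state, times, solver).  Every parameter has a
declared canonical unit; values may be given either as a bare number
(canonical unit assumed) or as ``{value: v, unit: "..."}``, in which
case the unit string must match the canonical one.  Unknown keys and
wrong units are rejected with the path of the offending key.  An empty
file yields the full laboratory defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .autotrophic import AutotrophicParams
from .heterotrophic import HeterotrophicParams
from .light import LightConfig, OpticalParams, PhotoResponseParams
from .state import CultureState

__all__ = ["RunConfig", "load_config", "save_config", "UNITS"]

#: Canonical unit for every configurable parameter ("-" = dimensionless).
UNITS: dict[str, str] = {
    "model": "-",
    "seed": "-",
    "optics.tau_c": "m^2 g^-1",
    "optics.alpha_g": "-",
    "optics.d_b": "m",
    "light.I0": "umol m^-2 s^-1",
    "light.L": "m",
    "light.n_surfaces": "-",
    "light.n_steps": "-",
    "autotrophic.mu_max_a": "h^-1",
    "autotrophic.mu_d_a": "L h^-1 g^-1",
    "autotrophic.ks": "umol m^-2 s^-1",
    "autotrophic.ki": "umol m^-2 s^-1",
    "heterotrophic.mu_max_h": "h^-1",
    "heterotrophic.mu_d_h": "L h^-1 g^-1",
    "heterotrophic.kq": "-",
    "heterotrophic.KN": "mg L^-1",
    "heterotrophic.KC": "mmol L^-1",
    "heterotrophic.Y_NX": "mg g^-1",
    "heterotrophic.Y_qX": "g^-1",
    "heterotrophic.Y_HX": "mL g^-1 h^-1",
    "heterotrophic.Y_OX": "L g^-1",
    "heterotrophic.Y_Od": "L g^-2",
    "heterotrophic.Y_CX": "mmol g^-1",
    "heterotrophic.Y_C": "mmol g^-1 h^-1",
    "heterotrophic.ks": "umol m^-2 s^-1",
    "heterotrophic.ki": "umol m^-2 s^-1",
    "heterotrophic.ks_h2": "umol m^-2 s^-1",
    "heterotrophic.ki_h2": "umol m^-2 s^-1",
    "initial_state.X": "g L^-1",
    "initial_state.N": "mg L^-1",
    "initial_state.q": "-",
    "initial_state.C": "mmol L^-1",
    "initial_state.O2": "L L^-1",
    "initial_state.H2": "mL L^-1",
    "times.t_end": "h",
    "times.n_points": "-",
    "solver.rtol": "-",
    "solver.atol": "-",
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one model run."""

    model: str = "heterotrophic"
    optics: OpticalParams = field(default_factory=OpticalParams)
    light: LightConfig = field(default_factory=LightConfig)
    autotrophic: AutotrophicParams = field(default_factory=AutotrophicParams)
    heterotrophic: HeterotrophicParams = field(default_factory=HeterotrophicParams)
    initial_state: CultureState = field(
        default_factory=lambda: CultureState(X=0.2, N=500.0, q=1.0, C=50.0, O2=0.0, H2=0.0)
    )
    t_end: float = 240.0
    n_points: int = 241
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("autotrophic", "heterotrophic"):
            raise ValueError("model must be 'autotrophic' or 'heterotrophic'")


class ConfigError(ValueError):
    """A configuration file problem, carrying the offending key path."""


def _scalar(raw, path: str):
    """Unwrap a value that may carry a unit annotation; check the unit."""
    canonical = UNITS[path]
    if isinstance(raw, dict):
        extra = set(raw) - {"value", "unit"}
        if extra:
            raise ConfigError(f"{path}: unexpected entries {sorted(extra)}")
        if "value" not in raw:
            raise ConfigError(f"{path}: annotated entry must carry 'value'")
        if "unit" not in raw:
            raise ConfigError(f"{path}: annotated entry must carry 'unit'")
        if str(raw["unit"]).strip() != canonical:
            raise ConfigError(
                f"{path}: unit {raw['unit']!r} does not match canonical {canonical!r}"
            )
        return raw["value"]
    return raw


def _block(doc: dict, name: str, keys: list[str]) -> dict:
    raw = doc.get(name, {}) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{name}: must be a mapping")
    unknown = set(raw) - set(keys)
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    return {k: _scalar(raw[k], f"{name}.{k}") for k in raw}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc or {})


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    top_keys = {"model", "seed", "optics", "light", "autotrophic",
                "heterotrophic", "initial_state", "times", "solver"}
    unknown = set(doc) - top_keys
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")

    def build(cls, kwargs, name):
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{name}: {exc}") from exc

    optics = build(OpticalParams, _block(doc, "optics", ["tau_c", "alpha_g", "d_b"]), "optics")
    light = build(LightConfig, _block(doc, "light", ["I0", "L", "n_surfaces", "n_steps"]), "light")

    auto_raw = _block(doc, "autotrophic", ["mu_max_a", "mu_d_a", "ks", "ki"])
    auto_defaults = AutotrophicParams()
    growth = build(
        PhotoResponseParams,
        {
            "ks": auto_raw.pop("ks", auto_defaults.growth_response.ks),
            "ki": auto_raw.pop("ki", auto_defaults.growth_response.ki),
        },
        "autotrophic",
    )
    auto = build(AutotrophicParams, {**auto_raw, "growth_response": growth}, "autotrophic")

    het_keys = ["mu_max_h", "mu_d_h", "kq", "KN", "KC", "Y_NX", "Y_qX", "Y_HX",
                "Y_OX", "Y_Od", "Y_CX", "Y_C", "ks", "ki", "ks_h2", "ki_h2"]
    het_raw = _block(doc, "heterotrophic", het_keys)
    het_defaults = HeterotrophicParams()
    het_growth = build(
        PhotoResponseParams,
        {
            "ks": het_raw.pop("ks", het_defaults.growth_response.ks),
            "ki": het_raw.pop("ki", het_defaults.growth_response.ki),
        },
        "heterotrophic",
    )
    het_h2 = build(
        PhotoResponseParams,
        {
            "ks": het_raw.pop("ks_h2", het_defaults.h2_response.ks),
            "ki": het_raw.pop("ki_h2", het_defaults.h2_response.ki),
        },
        "heterotrophic",
    )
    het = build(
        HeterotrophicParams,
        {**het_raw, "growth_response": het_growth, "h2_response": het_h2},
        "heterotrophic",
    )

    state = build(
        CultureState,
        {**dataclasses.asdict(RunConfig().initial_state),
         **_block(doc, "initial_state", ["X", "N", "q", "C", "O2", "H2"])},
        "initial_state",
    )

    times = _block(doc, "times", ["t_end", "n_points"])
    solver = _block(doc, "solver", ["rtol", "atol"])
    return RunConfig(
        model=_scalar(doc.get("model", "heterotrophic"), "model"),
        optics=optics,
        light=light,
        autotrophic=auto,
        heterotrophic=het,
        initial_state=state,
        t_end=float(times.get("t_end", 240.0)),
        n_points=int(times.get("n_points", 241)),
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-10)),
        seed=int(_scalar(doc.get("seed", 0), "seed")),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Serialize with full unit annotations on every parameter."""

    def ann(path: str, value):
        return {"value": value, "unit": UNITS[path]}

    het = cfg.heterotrophic
    return {
        "model": cfg.model,
        "seed": cfg.seed,
        "optics": {k: ann(f"optics.{k}", getattr(cfg.optics, k))
                   for k in ("tau_c", "alpha_g", "d_b")},
        "light": {k: ann(f"light.{k}", getattr(cfg.light, k))
                  for k in ("I0", "L", "n_surfaces", "n_steps")},
        "autotrophic": {
            "mu_max_a": ann("autotrophic.mu_max_a", cfg.autotrophic.mu_max_a),
            "mu_d_a": ann("autotrophic.mu_d_a", cfg.autotrophic.mu_d_a),
            "ks": ann("autotrophic.ks", cfg.autotrophic.growth_response.ks),
            "ki": ann("autotrophic.ki", cfg.autotrophic.growth_response.ki),
        },
        "heterotrophic": {
            **{k: ann(f"heterotrophic.{k}", getattr(het, k))
               for k in ("mu_max_h", "mu_d_h", "kq", "KN", "KC", "Y_NX", "Y_qX",
                          "Y_HX", "Y_OX", "Y_Od", "Y_CX", "Y_C")},
            "ks": ann("heterotrophic.ks", het.growth_response.ks),
            "ki": ann("heterotrophic.ki", het.growth_response.ki),
            "ks_h2": ann("heterotrophic.ks_h2", het.h2_response.ks),
            "ki_h2": ann("heterotrophic.ki_h2", het.h2_response.ki),
        },
        "initial_state": {k: ann(f"initial_state.{k}", getattr(cfg.initial_state, k))
                          for k in ("X", "N", "q", "C", "O2", "H2")},
        "times": {"t_end": ann("times.t_end", cfg.t_end),
                  "n_points": ann("times.n_points", cfg.n_points)},
        "solver": {"rtol": ann("solver.rtol", cfg.rtol),
                   "atol": ann("solver.atol", cfg.atol)},
    }


def save_config(cfg: RunConfig, path) -> None:
    """Write a fully annotated configuration; load_config inverts it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
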