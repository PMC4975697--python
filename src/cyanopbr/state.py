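"""Culture state vector and simulated time-courses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical ordering of the six state variables.
STATE_VARS = ("X", "N", "q", "C", "O2", "H2")

#: Units of the state variables (and of time) as used throughout.
STATE_UNITS = {
    "t": "h",
    "X": "g L^-1",       # biomass
    "N": "mg L^-1",      # nitrate
    "q": "-",            # normalized nitrogen quota
    "C": "mmol L^-1",    # glycerol
    "O2": "L L^-1",      # oxygen (model units, per litre of culture)
    "H2": "mL L^-1",     # cumulative hydrogen
}


@dataclass(frozen=True)
class CultureState:
    """One snapshot of the photo-heterotrophic culture.

    ``q`` is the nitrogen quota normalized by its nitrate-sufficient
    maximum, so growth ceases as ``q`` falls to the minimum quota ``kq``.
    """

    X: float
    N: float
    q: float
    C: float
    O2: float
    H2: float = 0.0

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("nitrogen quota q must be strictly positive")
        for name in ("X", "N", "C", "O2", "H2"):
            if getattr(self, name) < 0:
                raise ValueError(f"CultureState.{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CultureState":
        return cls(**dict(zip(STATE_VARS, map(float, y))))


class Trajectory:
    """A simulated time-course of one or more state variables.

    Thin wrapper over a :class:`pandas.DataFrame` with a ``t`` column
    (hours) followed by state columns; round-trips exactly through CSV.
    """

    def __init__(self, times: np.ndarray, values: dict[str, np.ndarray] | pd.DataFrame):
        times = np.asarray(times, dtype=float)
        frame = pd.DataFrame(values)
        if len(frame) != times.size:
            raise ValueError("times and values have mismatched lengths")
        frame.insert(0, "t", times)
        self.frame = frame

    @property
    def times(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    def __getitem__(self, var: str) -> np.ndarray:
        return self.frame[var].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "t"]

    def final_state(self) -> CultureState:
        if set(STATE_VARS) - set(self.frame.columns):
            raise ValueError("trajectory does not carry the full culture state")
        row = self.frame.iloc[-1]
        return CultureState(**{v: float(row[v]) for v in STATE_VARS})

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        frame = pd.read_csv(path)
        if "t" not in frame.columns:
            raise ValueError("trajectory file must have a 't' column")
        return cls(frame["t"].to_numpy(), frame.drop(columns="t"))
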