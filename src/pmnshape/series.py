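"""The R(t) order-parameter time series container and its CSV round trip.

R(t) is the relative radial roundness of a cell silhouette: the ratio of the
perimeter-derived circle-equivalent radius to the area-derived one.  Every
downstream measure (moments, Lyapunov exponent, spectra, embeddings,
wavelets) consumes this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATE_LABELS = ("idling", "treadmilling", "translocating", "transition", "unknown")


@dataclass
class RSeries:
    """A sampled roundness series R(t).

    Parameters
    ----------
    values : array-like of float
        One R value per frame, all strictly positive.
    dt : float
        Sampling interval in seconds (default 2 s, one frame every 2 s).
    cell_id : str
        Free-form label of the recorded cell.
    state_label : str
        One of ``idling, treadmilling, translocating, transition, unknown``.
    """

    values: np.ndarray
    dt: float = 2.0
    cell_id: str = ""
    state_label: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RSeries values must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.size and not np.all(self.values > 0):
            raise ValueError("R values must be strictly positive")
        if self.state_label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.state_label!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total recorded time in seconds."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def segment(self, start: int, stop: int) -> "RSeries":
        return RSeries(self.values[start:stop], dt=self.dt,
                       cell_id=self.cell_id, state_label=self.state_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "R": self.values})

    def to_csv(self, path) -> None:
        """Write the two-column (time_s, R) CSV with a one-line header."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell_id: str = "", state_label: str = "unknown") -> "RSeries":
        """Read a (time_s, R) CSV, or a single-column CSV of R values (dt
        then defaults to 2 s)."""
        df = pd.read_csv(path)
        if "R" in df.columns and "time_s" in df.columns:
            t = df["time_s"].to_numpy(float)
            dt = float(t[1] - t[0]) if len(t) > 1 else 2.0
            return cls(df["R"].to_numpy(float), dt=dt, cell_id=cell_id,
                       state_label=state_label)
        # single column of R values
        return cls(df.iloc[:, 0].to_numpy(float), dt=2.0, cell_id=cell_id,
                   state_label=state_label)
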