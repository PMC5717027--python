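"""Uniformly sampled stimulus streams."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError

__all__ = ["StimulusSeries"]


@dataclass
class StimulusSeries:
    """A uniformly sampled stream of m-dimensional stimulus values eta(t).

    ``values`` has shape (n, m); a 1-D array is promoted to (n, 1).
    ``dt`` is the sampling interval (seconds, or an arbitrary simulation
    unit) and ``t0`` the time of the first sample.
    """

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, np.newaxis]
        if v.ndim != 2 or v.shape[0] == 0:
            raise InvalidInputError("values must be a non-empty (n, m) array")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("stimulus values must be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidInputError(f"dt must be positive, got {self.dt}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def bounds(self, pad: float = 0.0) -> list[tuple[float, float]]:
        """Per-axis observed range, optionally padded on both sides."""
        lo = self.values.min(axis=0) - pad
        hi = self.values.max(axis=0) + pad
        return [(float(a), float(b)) for a, b in zip(lo, hi)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"v{j + 1}" for j in range(self.m)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        cols = [c for c in df.columns if c.startswith("v")]
        if "time" not in df.columns or not cols:
            raise FormatError(f"{path}: expected columns time, v1..vm")
        t = df["time"].to_numpy(dtype=float)
        if len(t) > 1:
            dts = np.diff(t)
            dt = float(np.median(dts))
            if dt <= 0 or not np.allclose(dts, dt, rtol=1e-6, atol=1e-9 * max(dt, 1.0)):
                raise FormatError(f"{path}: time column is not uniformly sampled")
        else:
            dt = 1.0
        return cls(values=df[cols].to_numpy(dtype=float), dt=dt, t0=float(t[0]))
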