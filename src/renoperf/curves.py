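"""Uniformly sampled time series — the universal currency of the package.

A :class:`Curve` holds a time axis in seconds on a uniform grid and one
value per sample (signal or concentration, arbitrary units).  All forward
models, noise injection and fitting operate on Curves sharing one grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Curve"]

#: relative tolerance on grid uniformity
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class Curve:
    """A uniformly sampled time series.

    Parameters
    ----------
    t : array-like
        Sample times in seconds, strictly increasing on a uniform grid
        (``t[0] == 0`` allowed).
    v : array-like
        One value per sample; signal or concentration in arbitrary units.
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("t and v must be one-dimensional")
        if len(t) != len(v):
            raise ValueError(f"len(t)={len(t)} != len(v)={len(v)}")
        if len(t) < 2:
            raise ValueError("a Curve needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("t and v must be finite")
        dt = np.diff(t)
        if dt[0] <= 0:
            raise ValueError("time axis must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _GRID_RTOL * max(abs(dt[0]), 1.0):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        """Grid spacing in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return len(self.t)

    def with_values(self, v: np.ndarray) -> "Curve":
        """A new Curve on the same grid with different values."""
        return Curve(self.t, np.asarray(v, dtype=float))

    def auc(self) -> float:
        """Trapezoidal area under the curve (value·seconds)."""
        return float(np.trapezoid(self.v, self.t))

    @staticmethod
    def from_spec(dt: float, n: int, v: np.ndarray | None = None) -> "Curve":
        """Curve on the grid ``0, dt, ..., (n-1)·dt`` (zeros if no values)."""
        t = np.arange(n) * float(dt)
        return Curve(t, np.zeros(n) if v is None else v)

    def same_grid(self, other: "Curve", rtol: float = _GRID_RTOL) -> bool:
        return self.n == other.n and abs(self.dt - other.dt) <= rtol * max(self.dt, 1.0)
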