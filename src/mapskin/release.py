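"""Tabulated in-vitro release kinetics.

Only drug that has actually been released from the dissolving needle matrix
can diffuse through skin, so the deposited dose in each sublayer is split
into an immobile depot and a mobile pool.  The depot-to-mobile transfer rate
is the time derivative of the measured cumulative release fraction, applied
to the sublayer's deposited dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReleaseTable"]


@dataclass(frozen=True)
class ReleaseTable:
    """Cumulative in-vitro release fraction versus time.

    ``times_h`` must be strictly increasing and ``fractions`` non-decreasing
    within [0, 1].  A (0, 0) anchor is prepended if the table does not start
    at t = 0.  Replicate standard deviations may ride along as metadata.
    """

    times_h: np.ndarray
    fractions: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.size == 0:
            raise ValueError("release table is empty")
        if t.size != f.size:
            raise ValueError("times and fractions must have equal length")
        if np.any(t < 0):
            raise ValueError("release times must be non-negative")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            f = np.concatenate([[0.0], f])
            if self.sd is not None:
                object.__setattr__(self, "sd", np.concatenate([[0.0], np.asarray(self.sd, float)]))
        if np.any(np.diff(t) <= 0):
            raise ValueError("release times must be strictly increasing")
        if f[0] != 0.0:
            raise ValueError("release fraction at t = 0 must be 0")
        if np.any(np.diff(f) < 0):
            raise ValueError("cumulative release fractions must be non-decreasing")
        if f[-1] > 1.0 + 1e-12:
            raise ValueError("cumulative release fraction cannot exceed 1")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "fractions", np.clip(f, 0.0, 1.0))

    def fraction_at(self, t_h):
        """Piecewise-linear cumulative fraction released by time ``t_h`` (h).

        Constant extrapolation at the final tabulated fraction beyond the
        table; a table whose last fraction is below 1 therefore never
        releases the remainder.
        """
        t = np.asarray(t_h, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = np.interp(t, self.times_h, self.fractions)
        return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))

    def rate_at(self, t_h):
        """Release rate (fraction per hour): slope of the active segment.

        Zero beyond the last tabulated point.  At a knot the right-hand
        segment's slope is used.
        """
        t = np.asarray(t_h, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        slopes = np.diff(self.fractions) / np.diff(self.times_h)
        idx = np.searchsorted(self.times_h, t, side="right") - 1
        idx = np.clip(idx, 0, slopes.size - 1)
        out = np.where(t >= self.times_h[-1], 0.0, slopes[idx])
        return out if out.ndim else float(out)

    @property
    def knots_h(self) -> np.ndarray:
        """Segment boundaries of the interpolant (h) — ODE restart points."""
        return self.times_h

    @classmethod
    def from_csv(cls, path) -> "ReleaseTable":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["cumulative_fraction"].to_numpy(), sd=sd)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_h": self.times_h, "cumulative_fraction": self.fractions})
        if self.sd is not None:
            df["sd"] = self.sd
        df.to_csv(path, index=False)
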