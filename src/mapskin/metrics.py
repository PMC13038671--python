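"""Model-validation metrics: AAFE, fold ratios, two-fold coverage, NCA.

AAFE (absolute average fold error) is the standard log-scale fold metric

    AAFE = 10 ** ( (1/n) * sum_i |log10(pred_i / obs_i)| )

which equals 1 for a perfect prediction and, for a single pair, the larger
of pred/obs and obs/pred.  Observed zeros cannot enter a fold metric; such
pairs are dropped and counted.  A model is conventionally accepted when
AAFE lies in [1, 2] and predicted/observed ratios fall within [0.5, 2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ObservedSeries",
    "PKSummary",
    "AAFEResult",
    "FoldRatio",
    "aafe",
    "fold_ratio",
    "twofold_coverage",
    "pk_parameters",
]


@dataclass(frozen=True)
class ObservedSeries:
    """Measured amount/concentration time series for one compartment."""

    times_h: np.ndarray
    values: np.ndarray
    compartment: str
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("observed values must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times_h, "compartment": self.compartment,
                           "value": self.values})
        if self.sd is not None:
            df["sd"] = np.asarray(self.sd, float)
        return df


class AAFEResult(NamedTuple):
    value: float
    n_used: int
    n_excluded: int

    def __float__(self) -> float:  # allows round(aafe(...), 2) style use
        return self.value


class FoldRatio(NamedTuple):
    ratio: float
    within_twofold: bool


@dataclass(frozen=True)
class PKSummary:
    """Non-compartmental summary of a concentration-time profile."""

    c_max: float
    t_max_h: float
    auc: dict  # (t0, t1) window (h) -> ng*h/ml


def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("no predicted/observed pairs supplied")
    return p, o


def aafe(predicted, observed) -> AAFEResult:
    """Absolute average fold error over paired positive values.

    Pairs with a zero (or negative) member are excluded, mirroring the
    practice of starting the comparison window after the last observed zero;
    their count is reported in ``n_excluded``.
    """
    p, o = _paired(predicted, observed)
    usable = (p > 0) & (o > 0)
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("no usable (positive) predicted/observed pairs for AAFE")
    logs = np.abs(np.log10(p[usable] / o[usable]))
    return AAFEResult(float(10 ** logs.mean()), int(usable.sum()), n_excluded)


def fold_ratio(predicted: float, observed: float) -> FoldRatio:
    """Predicted/observed ratio with the conventional [0.5, 2] gate."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    r = predicted / observed
    return FoldRatio(float(r), bool(0.5 <= r <= 2.0))


def twofold_coverage(predicted, observed) -> tuple[float, np.ndarray]:
    """Fraction of points whose predicted/observed ratio lies in [0.5, 2]."""
    p, o = _paired(predicted, observed)
    if np.any(o <= 0):
        raise ValueError("observed values must be positive for fold coverage")
    ratios = p / o
    flags = (ratios >= 0.5) & (ratios <= 2.0)
    return float(flags.mean()), flags


def pk_parameters(times_h, conc, windows) -> PKSummary:
    """C_max, t_max and windowed AUCs of a concentration-time profile.

    ``t_max`` is the first occurrence of the maximum.  AUC uses the linear
    trapezoid on the observation grid; window edges falling between grid
    points are filled in by linear interpolation and windows are clipped to
    the profile span.  Inserting interpolated points on a piecewise-linear
    profile therefore leaves every output unchanged.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size or t.size < 2:
        raise ValueError("need at least two profile points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("profile times must be strictly increasing")
    i_max = int(np.argmax(c))
    aucs = {}
    for t0, t1 in windows:
        lo, hi = max(t0, t[0]), min(t1, t[-1])
        if hi <= lo:
            raise ValueError(f"window ({t0}, {t1}) h does not overlap the profile")
        inner = t[(t > lo) & (t < hi)]
        grid = np.concatenate([[lo], inner, [hi]])
        vals = np.interp(grid, t, c)
        aucs[(t0, t1)] = float(np.trapezoid(vals, grid))
    return PKSummary(c_max=float(c[i_max]), t_max_h=float(t[i_max]), auc=aucs)
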