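"""Lumped systemic compartment coupled to the dermal model.

Drug cleared from the dermis enters a single well-stirred compartment of
volume ``V_d`` and is eliminated linearly with clearance ``CL_sys``:

    dC_p/dt = (clearance_flux_total - CL_sys * C_p) / V_d

Amounts in μg and volumes in litres make plasma concentration come out in
μg/l, which is numerically identical to ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DoseMap, NeedleGeometry, SkinStack
from .release import ReleaseTable
from .transport import Trajectory, TransportParams, simulate

__all__ = ["SystemicParams", "PlasmaProfile", "simulate_coupled"]


@dataclass(frozen=True)
class SystemicParams:
    """One-compartment disposition: volume of distribution and clearance."""

    v_d_l: float
    cl_sys_l_per_h: float

    def __post_init__(self) -> None:
        if self.v_d_l <= 0:
            raise ValueError("volume of distribution must be positive")
        if self.cl_sys_l_per_h < 0:
            raise ValueError("systemic clearance must be non-negative")


@dataclass(frozen=True)
class PlasmaProfile:
    """Plasma concentration-time profile (ng/ml)."""

    times_h: np.ndarray
    conc_ng_ml: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_ng_ml, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(c < -1e-12 * max(c.max(initial=0.0), 1.0)):
            raise ValueError("plasma concentrations must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "conc_ng_ml", c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times_h, "conc_ng_ml": self.conc_ng_ml})


def simulate_coupled(
    geom: NeedleGeometry,
    skin: SkinStack,
    dose_map: DoseMap,
    release: ReleaseTable,
    params: TransportParams,
    sys_params: SystemicParams,
    t_grid_h,
    **kwargs,
) -> tuple[Trajectory, PlasmaProfile]:
    """Run the dermal model with its clearance flux feeding the plasma pool.

    Requires ``in_vivo`` mode.  The returned trajectory carries the plasma
    and systemically-eliminated amounts, so the extended mass balance
    (depot + skin + plasma + eliminated = deposited dose) can be checked on
    it directly.
    """
    if params.mode != "in_vivo":
        raise ValueError("simulate_coupled requires in_vivo mode")
    traj = simulate(geom, skin, dose_map, release, params, t_grid_h,
                    systemic=sys_params, **kwargs)
    conc = traj.plasma_ug / sys_params.v_d_l  # μg/l == ng/ml
    # forgive solver-level undershoot around zero, fail on anything larger
    tol = 1e-9 * max(traj.deposited_dose_ug / sys_params.v_d_l, 1.0)
    if conc.min(initial=0.0) < -tol:
        raise ValueError(f"negative plasma concentration {conc.min():.3g} ng/ml")
    conc = np.clip(conc, 0.0, None)
    return traj, PlasmaProfile(times_h=np.asarray(t_grid_h, float), conc_ng_ml=conc)
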