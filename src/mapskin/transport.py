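"""Multilayer skin diffusion/partition transport.

The skin is a stack of three layers (SC, ED, DE), each discretised into
``n_sublayers * n_sections`` well-mixed sections of thickness ``dh``.
Within a layer, transfer between adjacent sections is Fickian:

    dA_n/dt = D_SL * (C_{n-1} - C_n) * Ar / dh_SL

with C = A / (dh * Ar).  Across the SC|ED and ED|DE interfaces the flux is a
two-film series conductance with partition ratio R = K_deep / K_shallow:

    rate = Ar * [ (D1/h1*)(D2/h2*) / ((D1/h1*) + R (D2/h2*)) ] * (R C1 - C2)

so the flux vanishes at partition equilibrium C2 = R C1.  ``h*`` is the
half-width of the section adjoining the interface (switchable to the full
layer thickness for comparison with the literal layer-resistance reading).

The deepest DE section drains into a perfect in-vitro sink (one-dimensional
diffusion, rate D_DE * C / dh * Ar) or, in vivo, every DE section loses drug
to the circulation at k_DE * dh * Ar * C_free.  Dermal binding reduces the
mobile concentration in DE: C_free = C / BF, applied to intra-DE diffusion,
the sink flux and clearance.  Hair-follicle and evaporation pathways carry
exactly zero flux.

The full system is linear with a piecewise-constant release input, so the
right-hand side is a constant matrix plus a per-segment source vector and
integration restarts at each release-table knot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .geometry import LAYERS, DoseMap, NeedleGeometry, SkinStack
from .release import ReleaseTable

__all__ = [
    "TransportParams",
    "SimState",
    "Trajectory",
    "SolverError",
    "simulate",
    "intra_layer_flux",
    "inter_layer_flux",
    "sink_flux",
    "clearance_flux",
    "constant_source_slab",
]

UM_TO_CM = 1e-4
H_TO_S = 3600.0

Mode = Literal["in_vitro", "in_vivo", "closed"]


class SolverError(RuntimeError):
    """ODE integration failure, carrying the time (h) at which it occurred."""

    def __init__(self, message: str, time_h: float):
        super().__init__(f"{message} (t = {time_h:.6g} h)")
        self.time_h = time_h


@dataclass(frozen=True)
class TransportParams:
    """Per-layer transport parameters.

    Diffusion coefficients in cm²/s, partition coefficients dimensionless
    (layer/vehicle), dermal clearance in 1/s, binding factor >= 1.
    ``mode`` selects the deep boundary: ``in_vitro`` (perfect sink),
    ``in_vivo`` (dermal clearance) or ``closed`` (no exit — diagnostic).
    """

    d_sc: float
    d_ed: float
    d_de: float
    k_sc: float
    k_ed: float
    k_de: float
    clearance_de: float = 0.0
    binding_factor: float = 1.0
    mode: Mode = "in_vitro"
    interface_half_width: bool = True
    clearance_deepest_only: bool = False

    def __post_init__(self) -> None:
        for name in ("d_sc", "d_ed", "d_de", "k_sc", "k_ed", "k_de"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clearance_de < 0:
            raise ValueError("clearance_de must be non-negative")
        if self.binding_factor < 1:
            raise ValueError("binding_factor must be >= 1")
        if self.mode not in ("in_vitro", "in_vivo", "closed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "in_vitro" and self.clearance_de != 0:
            raise ValueError("clearance_de must be 0 in in_vitro mode")

    def d(self, layer: str) -> float:
        return {"SC": self.d_sc, "ED": self.d_ed, "DE": self.d_de}[layer]

    def k(self, layer: str) -> float:
        return {"SC": self.k_sc, "ED": self.k_ed, "DE": self.k_de}[layer]


@dataclass
class SimState:
    """Drug amounts (μg) in every grid section plus the boundary pools."""

    amounts_ug: np.ndarray          # shape (3, n_sublayers, n_sections)
    depot_ug: np.ndarray            # shape (3, n_sublayers)
    sink_ug: float = 0.0
    cleared_ug: float = 0.0
    plasma_ug: float = 0.0
    eliminated_ug: float = 0.0
    time_h: float = 0.0

    def layer_amount_ug(self, layer: str) -> float:
        return float(self.amounts_ug[LAYERS.index(layer)].sum())

    def total_ug(self) -> float:
        return float(
            self.amounts_ug.sum() + self.depot_ug.sum()
            + self.sink_ug + self.cleared_ug + self.plasma_ug + self.eliminated_ug
        )


class _System:
    """Constant system matrix and release-source vector for one model setup."""

    def __init__(
        self,
        geom: NeedleGeometry,
        skin: SkinStack,
        dose_map: DoseMap,
        params: TransportParams,
        systemic=None,
    ):
        self.geom = geom
        self.skin = skin
        self.params = params
        self.systemic = systemic
        self.ns = skin.n_sublayers * skin.n_sections
        n = 3 * self.ns
        self.i_sink, self.i_cleared, self.i_plasma, self.i_elim = n, n + 1, n + 2, n + 3
        self.dim = n + 4
        ar = geom.array_area_cm2
        dh = {lay: skin.dh_um(lay) * UM_TO_CM for lay in LAYERS}
        bf = {"SC": 1.0, "ED": 1.0, "DE": params.binding_factor}

        # intra-layer Fickian chain (free concentration drives DE)
        M_intra = np.zeros((self.dim, self.dim))
        for li, lay in enumerate(LAYERS):
            c = params.d(lay) / (bf[lay] * dh[lay] ** 2)
            base = li * self.ns
            for j in range(1, self.ns):
                a, b = base + j - 1, base + j
                M_intra[a, a] -= c
                M_intra[a, b] += c
                M_intra[b, a] += c
                M_intra[b, b] -= c
        # layer interfaces: two-film series conductance, total C drives
        M_inter = np.zeros((self.dim, self.dim))
        for shallow, deep in (("SC", "ED"), ("ED", "DE")):
            i1 = LAYERS.index(shallow) * self.ns + self.ns - 1   # last shallow section
            i2 = LAYERS.index(deep) * self.ns                    # first deep section
            if params.interface_half_width:
                h1, h2 = dh[shallow] / 2.0, dh[deep] / 2.0
            else:
                h1 = skin.thickness_um[shallow] * UM_TO_CM
                h2 = skin.thickness_um[deep] * UM_TO_CM
            r = params.k(deep) / params.k(shallow)
            g1 = params.d(shallow) / h1
            g2 = params.d(deep) / h2
            cond = g1 * g2 / (g1 + r * g2)                       # cm/s
            # rate = Ar*cond*(R*C1 - C2) = cond*(R*A1/dh1 - A2/dh2)
            M_inter[i1, i1] -= cond * r / dh[shallow]
            M_inter[i1, i2] += cond / dh[deep]
            M_inter[i2, i1] += cond * r / dh[shallow]
            M_inter[i2, i2] -= cond / dh[deep]
        # deep boundary
        M_bound = np.zeros((self.dim, self.dim))
        i_last_de = 3 * self.ns - 1
        if params.mode == "in_vitro":
            s = params.d("DE") / (bf["DE"] * dh["DE"] ** 2)
            M_bound[i_last_de, i_last_de] -= s
            M_bound[self.i_sink, i_last_de] += s
        elif params.mode == "in_vivo":
            c = params.clearance_de / bf["DE"]
            target = self.i_plasma if systemic is not None else self.i_cleared
            de_base = 2 * self.ns
            if params.clearance_deepest_only:
                idxs = range(de_base + self.ns - skin.n_sections, de_base + self.ns)
            else:
                idxs = range(de_base, de_base + self.ns)
            for j in idxs:
                M_bound[j, j] -= c
                M_bound[target, j] += c
            if systemic is not None:
                kel = (systemic.cl_sys_l_per_h / H_TO_S) / systemic.v_d_l  # 1/s
                M_bound[self.i_plasma, self.i_plasma] -= kel
                M_bound[self.i_elim, self.i_plasma] += kel
        self.M_intra = M_intra
        self.M_inter = M_inter
        self.M_bound = M_bound
        self.M = M_intra + M_inter + M_bound

        # release source: deposited dose per sublayer spread over its sections
        w = np.zeros(self.dim)
        dose = geom.dose_ug
        self.sublayer_dose_ug = np.zeros((3, skin.n_sublayers))
        for lay, sub, frac in dose_map.sublayer_fractions:
            li = LAYERS.index(lay)
            self.sublayer_dose_ug[li, sub] = dose * frac
            base = li * self.ns + sub * skin.n_sections
            w[base:base + skin.n_sections] += dose * frac / skin.n_sections
        self.release_weights = w
        self.deposited_dose_ug = float(self.sublayer_dose_ug.sum())

    def unpack(self, y: np.ndarray, release_fraction: float, time_h: float) -> SimState:
        skin = self.skin
        amounts = y[: 3 * self.ns].reshape(3, skin.n_sublayers, skin.n_sections).copy()
        depot = self.sublayer_dose_ug * (1.0 - release_fraction)
        return SimState(
            amounts_ug=amounts,
            depot_ug=depot,
            sink_ug=float(y[self.i_sink]),
            cleared_ug=float(y[self.i_cleared]),
            plasma_ug=float(y[self.i_plasma]),
            eliminated_ug=float(y[self.i_elim]),
            time_h=time_h,
        )

    def pack_sections(self, amounts_ug: np.ndarray) -> np.ndarray:
        y = np.zeros(self.dim)
        y[: 3 * self.ns] = np.asarray(amounts_ug, float).reshape(-1)
        return y


@dataclass
class Trajectory:
    """Simulation output on the requested time grid.

    Holds the full packed states plus bookkeeping to reconstruct per-layer
    totals, pool amounts and the mass balance at every output time.
    """

    times_h: np.ndarray
    states: np.ndarray              # shape (n_times, dim)
    system: _System
    release: ReleaseTable | None
    solver_stats: dict

    def _sections(self) -> np.ndarray:
        ns = self.system.ns
        return self.states[:, : 3 * ns].reshape(len(self.times_h), 3,
                                                self.system.skin.n_sublayers,
                                                self.system.skin.n_sections)

    def layer_amounts_ug(self, layer: str) -> np.ndarray:
        return self._sections()[:, LAYERS.index(layer)].sum(axis=(1, 2))

    @property
    def sink_ug(self) -> np.ndarray:
        return self.states[:, self.system.i_sink]

    @property
    def cleared_ug(self) -> np.ndarray:
        return self.states[:, self.system.i_cleared]

    @property
    def plasma_ug(self) -> np.ndarray:
        return self.states[:, self.system.i_plasma]

    @property
    def eliminated_ug(self) -> np.ndarray:
        return self.states[:, self.system.i_elim]

    @property
    def depot_ug(self) -> np.ndarray:
        if self.release is None:
            return np.zeros_like(self.times_h)
        frac = np.asarray(self.release.fraction_at(self.times_h))
        return self.system.deposited_dose_ug * (1.0 - frac)

    def total_mass_ug(self) -> np.ndarray:
        return (self._sections().sum(axis=(1, 2, 3)) + self.depot_ug
                + self.sink_ug + self.cleared_ug + self.plasma_ug + self.eliminated_ug)

    @property
    def deposited_dose_ug(self) -> float:
        return self.system.deposited_dose_ug

    def mass_balance_rel_error(self) -> np.ndarray:
        dose = self.system.deposited_dose_ug
        if dose == 0:
            return np.abs(self.total_mass_ug())
        return np.abs(self.total_mass_ug() - dose) / dose

    def state_at(self, index: int) -> SimState:
        frac = self.release.fraction_at(self.times_h[index]) if self.release else 1.0
        return self.system.unpack(self.states[index], frac, self.times_h[index])

    def to_frame(self) -> pd.DataFrame:
        """Tidy trajectory: columns time_h, compartment, amount_ug."""
        cols = {
            "depot": self.depot_ug,
            "SC": self.layer_amounts_ug("SC"),
            "ED": self.layer_amounts_ug("ED"),
            "DE": self.layer_amounts_ug("DE"),
            "sink": self.sink_ug,
            "cleared": self.cleared_ug,
            "plasma": self.plasma_ug,
            "eliminated": self.eliminated_ug,
        }
        frames = [
            pd.DataFrame({"time_h": self.times_h, "compartment": name, "amount_ug": vals})
            for name, vals in cols.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def sample(self, compartment: str, times_h) -> np.ndarray:
        """Linear interpolation of one compartment's amount at given times."""
        series = {
            "SC": self.layer_amounts_ug("SC"),
            "ED": self.layer_amounts_ug("ED"),
            "DE": self.layer_amounts_ug("DE"),
            "sink": self.sink_ug,
            "cleared": self.cleared_ug,
            "plasma": self.plasma_ug,
            "depot": self.depot_ug,
        }[compartment]
        return np.interp(np.asarray(times_h, float), self.times_h, series)


def simulate(
    geom: NeedleGeometry,
    skin: SkinStack,
    dose_map: DoseMap,
    release: ReleaseTable,
    params: TransportParams,
    t_grid_h,
    *,
    systemic=None,
    initial_sections_ug: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol_scale: float = 1e-12,
) -> Trajectory:
    """Integrate the full MAP skin-transport system over ``t_grid_h`` (hours).

    The stiff-capable LSODA integrator is used with the exact (constant)
    Jacobian; integration restarts at every release-table knot, where the
    depot-to-mobile source rate jumps.  ``initial_sections_ug`` bypasses the
    dose map and release coupling entirely (used for diagnostic runs from an
    arbitrary state — the depot is then empty and no release source acts).
    """
    t_grid_h = np.asarray(t_grid_h, dtype=float)
    if t_grid_h.ndim != 1 or t_grid_h.size == 0:
        raise ValueError("t_grid_h must be a non-empty 1-D array")
    if t_grid_h[0] < 0 or np.any(np.diff(t_grid_h) <= 0):
        raise ValueError("t_grid_h must be increasing and start at t >= 0")

    sys_ = _System(geom, skin, dose_map, params, systemic=systemic)
    y0 = np.zeros(sys_.dim)
    use_release: ReleaseTable | None = release
    if initial_sections_ug is not None:
        y0 = sys_.pack_sections(initial_sections_ug)
        sys_.deposited_dose_ug = float(y0.sum())
        sys_.sublayer_dose_ug = np.zeros_like(sys_.sublayer_dose_ug)
        use_release = None

    dose = sys_.deposited_dose_ug
    atol = max(atol_scale * dose, 1e-18)
    t_end = t_grid_h[-1]

    # segment boundaries: release knots inside (0, t_end) plus endpoints
    if use_release is not None:
        knots = use_release.knots_h
        seg = np.unique(np.concatenate([[0.0, t_end], knots[(knots > 0) & (knots < t_end)]]))
    else:
        seg = np.array([0.0, t_end])

    out_states = np.empty((t_grid_h.size, sys_.dim))
    if t_grid_h[0] == 0.0:
        out_states[0] = y0
        next_out = 1
    else:
        next_out = 0

    M = sys_.M
    nfev = 0
    y = y0
    for ts, te in zip(seg[:-1], seg[1:]):
        if use_release is not None:
            rate_per_s = use_release.rate_at(0.5 * (ts + te)) / H_TO_S
            b = sys_.release_weights * rate_per_s
        else:
            b = np.zeros(sys_.dim)
        mask = (t_grid_h > ts) & (t_grid_h <= te)
        t_eval = np.unique(np.concatenate([t_grid_h[mask], [te]])) * H_TO_S
        sol = solve_ivp(
            lambda t, yv: M @ yv + b,
            (ts * H_TO_S, te * H_TO_S),
            y,
            method="LSODA",
            jac=lambda t, yv: M,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed: {sol.message}", time_h=sol.t[-1] / H_TO_S
                              if sol.t.size else ts)
        nfev += sol.nfev
        sel = np.isin(sol.t, t_grid_h[mask] * H_TO_S)
        n_sel = int(sel.sum())
        out_states[next_out:next_out + n_sel] = sol.y[:, sel].T
        next_out += n_sel
        y = sol.y[:, -1]

    min_amount = out_states[:, : 3 * sys_.ns].min() if sys_.ns else 0.0
    if dose > 0 and min_amount < -1e-9 * dose:
        raise SolverError(
            f"negative section amount {min_amount:.3g} μg beyond tolerance", time_h=t_end
        )
    stats = {"nfev": nfev, "dim": sys_.dim, "segments": len(seg) - 1,
             "rtol": rtol, "atol": atol}
    return Trajectory(times_h=t_grid_h, states=out_states, system=sys_,
                      release=use_release, solver_stats=stats)


# ---------------------------------------------------------------------------
# Single-mechanism flux evaluations on a SimState (μg/h).  These re-use the
# same matrix construction as the integrator so the tested quantities are the
# ones actually integrated.

def _empty_dose_map(skin: SkinStack) -> DoseMap:
    fr = tuple((lay, s, 0.0) for lay in LAYERS for s in range(skin.n_sublayers))
    return DoseMap(sublayer_fractions=fr, undeposited_fraction=1.0)


def _state_system(state: SimState, params: TransportParams, skin: SkinStack,
                  geom: NeedleGeometry) -> tuple[_System, np.ndarray]:
    sys_ = _System(geom, skin, _empty_dose_map(skin), params)
    y = sys_.pack_sections(state.amounts_ug)
    return sys_, y


def intra_layer_flux(state: SimState, params: TransportParams, skin: SkinStack,
                     geom: NeedleGeometry) -> dict[str, np.ndarray]:
    """Per-section net Fickian rate (μg/h) from intra-layer diffusion only.

    Antisymmetric by construction: what leaves a section enters its
    neighbour, so each layer's vector sums to zero.
    """
    sys_, y = _state_system(state, params, skin, geom)
    rates = (sys_.M_intra @ y) * H_TO_S
    ns = sys_.ns
    return {lay: rates[LAYERS.index(lay) * ns:(LAYERS.index(lay) + 1) * ns] for lay in LAYERS}


def inter_layer_flux(state: SimState, params: TransportParams, skin: SkinStack,
                     geom: NeedleGeometry) -> tuple[float, float]:
    """Net interface rates (μg/h): (SC→ED, ED→DE); positive flows deeper."""
    ar = geom.array_area_cm2
    out = []
    for shallow, deep in (("SC", "ED"), ("ED", "DE")):
        dh1 = skin.dh_um(shallow) * UM_TO_CM
        dh2 = skin.dh_um(deep) * UM_TO_CM
        if params.interface_half_width:
            h1, h2 = dh1 / 2.0, dh2 / 2.0
        else:
            h1 = skin.thickness_um[shallow] * UM_TO_CM
            h2 = skin.thickness_um[deep] * UM_TO_CM
        a1 = state.amounts_ug[LAYERS.index(shallow)].reshape(-1)[-1]
        a2 = state.amounts_ug[LAYERS.index(deep)].reshape(-1)[0]
        c1 = a1 / (dh1 * ar)
        c2 = a2 / (dh2 * ar)
        r = params.k(deep) / params.k(shallow)
        g1 = params.d(shallow) / h1
        g2 = params.d(deep) / h2
        cond = g1 * g2 / (g1 + r * g2)
        out.append(ar * cond * (r * c1 - c2) * H_TO_S)
    return out[0], out[1]


def sink_flux(state: SimState, params: TransportParams, skin: SkinStack,
              geom: NeedleGeometry) -> float:
    """Rate (μg/h) out of the deepest DE section into the in-vitro sink."""
    if params.mode != "in_vitro":
        raise ValueError("sink_flux requires in_vitro mode")
    dh = skin.dh_um("DE") * UM_TO_CM
    a_last = state.amounts_ug[2].reshape(-1)[-1]
    c_free = a_last / (dh * geom.array_area_cm2) / params.binding_factor
    return params.d_de * c_free / dh * geom.array_area_cm2 * H_TO_S


def clearance_flux(state: SimState, params: TransportParams, skin: SkinStack,
                   geom: NeedleGeometry) -> float:
    """Total dermal clearance rate (μg/h) into the systemic pool."""
    if params.mode != "in_vivo":
        raise ValueError("clearance_flux requires in_vivo mode")
    amounts_de = state.amounts_ug[2]
    if params.clearance_deepest_only:
        amounts = amounts_de[-1].sum()
    else:
        amounts = amounts_de.sum()
    return params.clearance_de * amounts / params.binding_factor * H_TO_S


def constant_source_slab(
    d_cm2_s: float,
    h_um: float,
    c_donor_ug_cm3: float,
    ar_cm2: float,
    n_sections: int,
    t_grid_h,
    partition: float = 1.0,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Permeation through a single membrane from a constant donor solution.

    Classic Franz-cell configuration: the donor concentration is clamped at
    the upper face (membrane surface concentration ``K * C_donor``), the
    lower face is a perfect sink.  Both boundary resistances use the section
    half-width, so the discrete steady-state flux equals the Fickian value
    ``D * K * C_donor * Ar / h`` exactly and the cumulative permeated amount
    approaches the lag-time asymptote ``(D K C Ar / h) * (t - h²/(6 D))``.

    Returns a frame with time_h, flux_ug_per_h and cumulative_ug.
    """
    t_grid_h = np.asarray(t_grid_h, dtype=float)
    h = h_um * UM_TO_CM
    dh = h / n_sections
    c_surface = partition * c_donor_ug_cm3
    n = n_sections
    M = np.zeros((n + 1, n + 1))
    g = d_cm2_s / dh ** 2               # inner-link coefficient (1/s)
    gb = d_cm2_s / (dh * dh / 2.0)      # half-width boundary coefficient
    b = np.zeros(n + 1)
    b[0] = gb * c_surface * dh * ar_cm2  # inflow from clamped donor face
    M[0, 0] -= gb
    for j in range(1, n):
        M[j - 1, j - 1] -= g
        M[j - 1, j] += g
        M[j, j - 1] += g
        M[j, j] -= g
    M[n - 1, n - 1] -= gb
    M[n, n - 1] += gb                   # receiver (perfect sink) accumulator
    sol = solve_ivp(
        lambda t, y: M @ y + b, (0.0, t_grid_h[-1] * H_TO_S), np.zeros(n + 1),
        method="LSODA", jac=lambda t, y: M, t_eval=t_grid_h * H_TO_S,
        rtol=rtol, atol=1e-15,
    )
    if not sol.success:
        raise SolverError(f"slab integration failed: {sol.message}", time_h=t_grid_h[-1])
    flux = gb * sol.y[n - 1] * H_TO_S   # μg/h into the receiver
    return pd.DataFrame({
        "time_h": t_grid_h,
        "flux_ug_per_h": flux,
        "cumulative_ug": sol.y[n],
    })
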