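"""Ready-made MAP scenarios and synthetic observation generators.

Three labelled bundles mirror the study formulations:

* ``LOR`` — loratadine, drug-only needles, 0.5 mg/patch, prolonged release
  (complete by 24 h), simulated in vitro (Franz-cell sink);
* ``CPM`` — chlorpheniramine maleate in a polymeric matrix, 0.1 mg/patch,
  burst release (39.3 % at 5 min, complete at 30 min), in vitro;
* ``ITZ`` — itraconazole, 14 x 14 array, 4.1 mg/patch, very slow release
  (complete by 120 h), simulated in vivo with dermal clearance feeding a
  lumped plasma compartment.

All share the 5 x 5-era needle geometry (500 μm height, 333 μm base,
~70 % insertion) and porcine-ear layer thicknesses.  Diffusion/partition
values that were reported after optimisation are used as the bundle
defaults; the remaining coefficients (SC/ED diffusion, SC partition, CPM
and ITZ partition set, dermal clearance rate, minipig disposition) are
order-of-magnitude stand-ins chosen for physiological plausibility — see
docs/methods.md — and must not be read as measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import NeedleGeometry, SkinStack, DoseMap, dose_partition
from .metrics import ObservedSeries
from .release import ReleaseTable
from .systemic import PlasmaProfile, SystemicParams, simulate_coupled
from .transport import Trajectory, TransportParams, simulate

__all__ = [
    "ScenarioBundle",
    "make_scenario",
    "make_noisy_observations",
    "simulate_bundle",
    "bundle_predictor",
    "with_transport",
    "with_mode",
    "TABLE_STARTING",
    "TABLE_OPTIMAL",
]

#: Starting and optimised values for the sensitive parameters of each
#: formulation (diffusion in cm²/s, thickness in μm, K and BF dimensionless).
TABLE_STARTING: dict[str, dict[str, float]] = {
    "LOR": {"D_de": 3.32e-8, "K_de": 44.67, "K_ed": 44.67, "h_de": 1500.0, "h_ed": 72.0},
    "CPM": {"D_de": 2.52e-7, "h_de": 1500.0, "h_ed": 72.0},
    "ITZ": {"BF": 2101.87},
}

TABLE_OPTIMAL: dict[str, dict[str, float]] = {
    "LOR": {"D_de": 5.34e-8, "K_de": 38.55, "K_ed": 46.00, "h_de": 1439.42, "h_ed": 85.0},
    "CPM": {"D_de": 2.79e-7, "h_de": 1237.02, "h_ed": 80.0},
    "ITZ": {"BF": 1262.99},
}

#: Stand-in dermal clearance rate (1/s) for in-vivo runs — not a reported value.
DEFAULT_CLEARANCE_DE = 5e-3


@dataclass(frozen=True)
class ScenarioBundle:
    """Internally consistent inputs for one simulated MAP experiment."""

    label: str
    seed: int
    geometry: NeedleGeometry
    skin: SkinStack
    transport: TransportParams
    release: ReleaseTable
    systemic: SystemicParams | None = None


def _first_order_table(t_end_h: float, k_per_h: float, n_points: int = 13) -> ReleaseTable:
    """First-order release curve normalised to complete release at ``t_end_h``."""
    t = np.linspace(0.0, t_end_h, n_points)
    f = (1 - np.exp(-k_per_h * t)) / (1 - np.exp(-k_per_h * t_end_h))
    f[-1] = 1.0
    return ReleaseTable(times_h=t, fractions=f)


def _release_table(label: str) -> ReleaseTable:
    if label == "CPM":
        # burst anchors: 39.3 % at 5 min, complete at 30 min, linear infill
        return ReleaseTable(times_h=np.array([0.0, 5 / 60, 0.5]),
                            fractions=np.array([0.0, 0.393, 1.0]))
    if label == "LOR":
        return _first_order_table(24.0, k_per_h=0.25)
    if label == "ITZ":
        return _first_order_table(120.0, k_per_h=0.05)
    raise ValueError(f"unknown scenario label {label!r}")


def make_scenario(label: str, seed: int = 1234) -> ScenarioBundle:
    """Build the labelled scenario bundle (``LOR``, ``CPM`` or ``ITZ``)."""
    label = label.upper()
    if label not in ("LOR", "CPM", "ITZ"):
        raise ValueError(f"unknown scenario label {label!r}")

    if label == "ITZ":
        geom = NeedleGeometry(height_um=500.0, base_width_um=333.0, n_needles=196,
                              array_area_cm2=196 / 25.0, dose_mg=4.1,
                              penetration_fraction=0.7)
    else:
        dose = 0.5 if label == "LOR" else 0.1
        geom = NeedleGeometry(height_um=500.0, base_width_um=333.0, n_needles=25,
                              array_area_cm2=1.0, dose_mg=dose,
                              penetration_fraction=0.7)

    opt = TABLE_OPTIMAL[label]
    skin = SkinStack(h_sc_um=21.0, h_ed_um=opt.get("h_ed", 72.0),
                     h_de_um=opt.get("h_de", 1500.0))

    if label == "LOR":
        transport = TransportParams(
            d_sc=1e-9, d_ed=1e-8, d_de=opt["D_de"],
            k_sc=44.67, k_ed=opt["K_ed"], k_de=opt["K_de"],
            mode="in_vitro",
        )
        systemic = None
    elif label == "CPM":
        transport = TransportParams(
            d_sc=1e-9, d_ed=1e-7, d_de=opt["D_de"],
            k_sc=1.0, k_ed=1.0, k_de=1.0,
            mode="in_vitro",
        )
        systemic = None
    else:  # ITZ, in vivo
        transport = TransportParams(
            d_sc=1e-9, d_ed=1e-8, d_de=3.32e-8,
            k_sc=50.0, k_ed=50.0, k_de=50.0,
            clearance_de=DEFAULT_CLEARANCE_DE,
            binding_factor=opt["BF"],
            mode="in_vivo",
        )
        systemic = SystemicParams(v_d_l=40.0, cl_sys_l_per_h=0.8)

    return ScenarioBundle(label=label, seed=seed, geometry=geom, skin=skin,
                          transport=transport, release=_release_table(label),
                          systemic=systemic)


def with_mode(bundle: ScenarioBundle, mode: str) -> ScenarioBundle:
    """Switch a bundle between in-vitro and in-vivo boundary conditions."""
    if mode == "in_vitro":
        transport = replace(bundle.transport, mode=mode, clearance_de=0.0)
    elif mode == "in_vivo":
        clear = bundle.transport.clearance_de or DEFAULT_CLEARANCE_DE
        transport = replace(bundle.transport, mode=mode, clearance_de=clear)
    elif mode == "closed":
        transport = replace(bundle.transport, mode=mode, clearance_de=0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    systemic = bundle.systemic
    if mode == "in_vivo" and systemic is None:
        systemic = SystemicParams(v_d_l=40.0, cl_sys_l_per_h=0.8)
    return replace(bundle, transport=transport, systemic=systemic)


# parameter-name -> how it modifies the bundle
_TRANSPORT_KEYS = {"D_sc": "d_sc", "D_ed": "d_ed", "D_de": "d_de",
                   "K_sc": "k_sc", "K_ed": "k_ed", "K_de": "k_de",
                   "BF": "binding_factor", "k_clear": "clearance_de"}
_SKIN_KEYS = {"h_sc": "h_sc_um", "h_ed": "h_ed_um", "h_de": "h_de_um"}
_GEOM_KEYS = {"dose_mg": "dose_mg", "f_p": "penetration_fraction"}


def with_transport(bundle: ScenarioBundle, **overrides) -> ScenarioBundle:
    """New bundle with named parameters replaced.

    Accepts transport names (``D_de``, ``K_ed``, ``BF``, ``k_clear``, ...),
    skin thicknesses (``h_sc``/``h_ed``/``h_de``, μm) and geometry fields
    (``dose_mg``, ``f_p``).
    """
    tr, sk, ge = {}, {}, {}
    for name, value in overrides.items():
        if name in _TRANSPORT_KEYS:
            tr[_TRANSPORT_KEYS[name]] = value
        elif name in _SKIN_KEYS:
            sk[_SKIN_KEYS[name]] = value
        elif name in _GEOM_KEYS:
            ge[_GEOM_KEYS[name]] = value
        else:
            raise KeyError(f"unknown parameter {name!r}")
    out = bundle
    if tr:
        out = replace(out, transport=replace(out.transport, **tr))
    if sk:
        out = replace(out, skin=replace(out.skin, **sk))
    if ge:
        out = replace(out, geometry=replace(out.geometry, **ge))
    return out


def bundle_params(bundle: ScenarioBundle) -> dict[str, float]:
    """Flat named-parameter view of a bundle (inverse of ``with_transport``)."""
    t, s, g = bundle.transport, bundle.skin, bundle.geometry
    return {
        "D_sc": t.d_sc, "D_ed": t.d_ed, "D_de": t.d_de,
        "K_sc": t.k_sc, "K_ed": t.k_ed, "K_de": t.k_de,
        "BF": t.binding_factor, "k_clear": t.clearance_de,
        "h_sc": s.h_sc_um, "h_ed": s.h_ed_um, "h_de": s.h_de_um,
        "dose_mg": g.dose_mg, "f_p": g.penetration_fraction,
    }


def simulate_bundle(bundle: ScenarioBundle, t_grid_h, *,
                    normalisation: str = "inserted", **kwargs) -> Trajectory:
    """Dose-partition and integrate one bundle on the requested grid."""
    dm = dose_partition(bundle.geometry, bundle.skin, normalisation=normalisation)
    systemic = bundle.systemic if bundle.transport.mode == "in_vivo" else None
    return simulate(bundle.geometry, bundle.skin, dm, bundle.release,
                    bundle.transport, t_grid_h, systemic=systemic, **kwargs)


def plasma_profile(bundle: ScenarioBundle, t_grid_h, **kwargs) -> tuple[Trajectory, PlasmaProfile]:
    """Coupled dermal + systemic simulation returning the plasma curve."""
    if bundle.systemic is None:
        raise ValueError("bundle has no systemic parameters")
    dm = dose_partition(bundle.geometry, bundle.skin)
    return simulate_coupled(bundle.geometry, bundle.skin, dm, bundle.release,
                            bundle.transport, bundle.systemic, t_grid_h, **kwargs)


def bundle_predictor(bundle: ScenarioBundle,
                     series_spec: Sequence[tuple[str, np.ndarray]]):
    """Build a ``predict(params) -> values`` callable for fitting.

    ``series_spec`` lists ``(compartment, times_h)`` pairs; predictions are
    concatenated in that order.  Parameter names follow ``with_transport``.
    Compartment ``plasma_ng_ml`` yields concentration, everything else
    amounts in μg.
    """
    all_times = np.unique(np.concatenate([[0.0]] + [np.asarray(t, float)
                                                    for _, t in series_spec]))

    def predict(params: Mapping[str, float]) -> np.ndarray:
        b = with_transport(bundle, **dict(params))
        traj = simulate_bundle(b, all_times)
        chunks = []
        for comp, times in series_spec:
            if comp == "plasma_ng_ml":
                if b.systemic is None:
                    raise ValueError("plasma concentration needs systemic parameters")
                vals = traj.sample("plasma", times) / b.systemic.v_d_l
            else:
                vals = traj.sample(comp, times)
            chunks.append(vals)
        return np.concatenate(chunks)

    return predict


def make_noisy_observations(
    bundle: ScenarioBundle,
    noise_cv: float,
    seed: int,
    times_h,
    compartments: Sequence[str] | None = None,
) -> list[ObservedSeries]:
    """Synthetic observed series: model output times seeded lognormal noise.

    The multiplicative noise has unit mean and coefficient of variation
    ``noise_cv`` (sigma² = ln(1 + cv²)); ``noise_cv = 0`` reproduces the
    model exactly.  Identical seeds give identical series.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(times_h, dtype=float)
    if compartments is None:
        compartments = (("plasma",) if bundle.transport.mode == "in_vivo"
                        else ("ED", "DE", "sink"))
    t_grid = np.unique(np.concatenate([[0.0], times]))
    traj = simulate_bundle(bundle, t_grid)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    out = []
    for comp in compartments:
        clean = traj.sample(comp, times)
        factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=times.size)
        out.append(ObservedSeries(times_h=times, values=clean * factors, compartment=comp))
    return out
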