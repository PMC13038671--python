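"""Flat-file configuration and CSV readers/writers.

A scenario directory holds a flat key-value ``config.yaml`` plus a
``release.csv`` table; all time columns are in hours, amounts in μg,
concentrations in ng/ml, comma-separated with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import NeedleGeometry, SkinStack, DoseMap, dose_partition
from .metrics import ObservedSeries
from .release import ReleaseTable
from .systemic import SystemicParams
from .scenarios import ScenarioBundle
from .transport import Trajectory, TransportParams

__all__ = [
    "write_scenario_dir",
    "read_scenario_dir",
    "write_dose_map_csv",
    "read_observed_csv",
    "write_observed_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _bundle_config(bundle: ScenarioBundle) -> dict:
    g, s, t = bundle.geometry, bundle.skin, bundle.transport
    cfg = {
        "label": bundle.label,
        "seed": bundle.seed,
        "height_um": g.height_um,
        "base_width_um": g.base_width_um,
        "n_needles": g.n_needles,
        "array_area_cm2": g.array_area_cm2,
        "dose_mg": g.dose_mg,
        "penetration_fraction": g.penetration_fraction,
        "h_sc_um": s.h_sc_um,
        "h_ed_um": s.h_ed_um,
        "h_de_um": s.h_de_um,
        "n_sublayers": s.n_sublayers,
        "n_sections": s.n_sections,
        "D_sc": t.d_sc,
        "D_ed": t.d_ed,
        "D_de": t.d_de,
        "K_sc": t.k_sc,
        "K_ed": t.k_ed,
        "K_de": t.k_de,
        "clearance_de": t.clearance_de,
        "binding_factor": t.binding_factor,
        "mode": t.mode,
        "interface_half_width": t.interface_half_width,
        "clearance_deepest_only": t.clearance_deepest_only,
        "release_csv": "release.csv",
    }
    if bundle.systemic is not None:
        cfg["v_d_l"] = bundle.systemic.v_d_l
        cfg["cl_sys_l_per_h"] = bundle.systemic.cl_sys_l_per_h
    return cfg


def write_scenario_dir(bundle: ScenarioBundle, path) -> Path:
    """Write config.yaml, release.csv and dose_map.csv for one scenario."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(_bundle_config(bundle), fh, sort_keys=False)
    bundle.release.to_csv(path / "release.csv")
    write_dose_map_csv(dose_partition(bundle.geometry, bundle.skin),
                       path / "dose_map.csv")
    return path


def read_scenario_dir(path) -> ScenarioBundle:
    path = Path(path)
    cfg_file = path / "config.yaml"
    if not cfg_file.exists():
        raise FileNotFoundError(f"no config.yaml in {path}")
    with open(cfg_file) as fh:
        cfg = yaml.safe_load(fh)
    geom = NeedleGeometry(
        height_um=float(cfg["height_um"]),
        base_width_um=float(cfg["base_width_um"]),
        n_needles=int(cfg["n_needles"]),
        array_area_cm2=float(cfg["array_area_cm2"]),
        dose_mg=float(cfg["dose_mg"]),
        penetration_fraction=float(cfg["penetration_fraction"]),
    )
    skin = SkinStack(
        h_sc_um=float(cfg["h_sc_um"]),
        h_ed_um=float(cfg["h_ed_um"]),
        h_de_um=float(cfg["h_de_um"]),
        n_sublayers=int(cfg.get("n_sublayers", 4)),
        n_sections=int(cfg.get("n_sections", 10)),
    )
    transport = TransportParams(
        d_sc=float(cfg["D_sc"]), d_ed=float(cfg["D_ed"]), d_de=float(cfg["D_de"]),
        k_sc=float(cfg["K_sc"]), k_ed=float(cfg["K_ed"]), k_de=float(cfg["K_de"]),
        clearance_de=float(cfg.get("clearance_de", 0.0)),
        binding_factor=float(cfg.get("binding_factor", 1.0)),
        mode=cfg.get("mode", "in_vitro"),
        interface_half_width=bool(cfg.get("interface_half_width", True)),
        clearance_deepest_only=bool(cfg.get("clearance_deepest_only", False)),
    )
    release = ReleaseTable.from_csv(path / cfg.get("release_csv", "release.csv"))
    systemic = None
    if "v_d_l" in cfg:
        systemic = SystemicParams(v_d_l=float(cfg["v_d_l"]),
                                  cl_sys_l_per_h=float(cfg["cl_sys_l_per_h"]))
    return ScenarioBundle(label=cfg.get("label", "custom"), seed=int(cfg.get("seed", 0)),
                          geometry=geom, skin=skin, transport=transport,
                          release=release, systemic=systemic)


def write_dose_map_csv(dose_map: DoseMap, path) -> None:
    rows = [{"layer": lay, "sublayer": sub, "fraction": frac}
            for lay, sub, frac in dose_map.sublayer_fractions]
    df = pd.DataFrame(rows, columns=["layer", "sublayer", "fraction"])
    df.to_csv(path, index=False)


def write_observed_csv(series_list, path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(path, index=False)


def read_observed_csv(path) -> list[ObservedSeries]:
    df = pd.read_csv(path)
    out = []
    for comp, grp in df.groupby("compartment", sort=False):
        grp = grp.sort_values("time_h")
        sd = grp["sd"].to_numpy() if "sd" in grp.columns else None
        out.append(ObservedSeries(times_h=grp["time_h"].to_numpy(),
                                  values=grp["value"].to_numpy(),
                                  compartment=str(comp), sd=sd))
    return out


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
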