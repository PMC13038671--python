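"""MAP needle geometry and the geometric dose-to-sublayer mapping.

A dissolvable MAP carries its dose distributed through the needle matrix.
On application the needles insert to a fraction ``f_p`` of their height, so
the drug contained in the inserted tip volume ends up physically located in
whichever skin sublayer the corresponding slice of needle sits in.  For a
pyramidal needle the volume between the apex and a plane at distance ``d``
from the tip is ``(d / H)**3`` of the whole needle, which gives a closed-form
cumulative dose profile along the insertion axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "NeedleGeometry",
    "SkinStack",
    "DoseMap",
    "needle_cumulative_volume",
    "dose_partition",
]

LAYERS = ("SC", "ED", "DE")


@dataclass(frozen=True)
class NeedleGeometry:
    """Pyramidal microneedle array description.

    Parameters
    ----------
    height_um : float
        Needle height (μm).
    base_width_um : float
        Needle base width (μm).
    n_needles : int
        Number of needles in the array.
    array_area_cm2 : float
        Application surface area of the patch, ``Ar`` (cm²).
    dose_mg : float
        Total drug load of the patch (mg).
    penetration_fraction : float
        Fraction of the needle height that inserts into skin, in (0, 1].
    """

    height_um: float
    base_width_um: float
    n_needles: int
    array_area_cm2: float
    dose_mg: float
    penetration_fraction: float

    def __post_init__(self) -> None:
        if self.height_um <= 0:
            raise ValueError("needle height must be positive")
        if self.base_width_um <= 0:
            raise ValueError("needle base width must be positive")
        if self.n_needles < 1:
            raise ValueError("need at least one needle")
        if self.array_area_cm2 <= 0:
            raise ValueError("array area must be positive")
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")
        if not 0 < self.penetration_fraction <= 1:
            raise ValueError("penetration fraction must be in (0, 1]")

    @property
    def inserted_length_um(self) -> float:
        """Inserted needle length ``L_ins = f_p * H`` (μm)."""
        return self.penetration_fraction * self.height_um

    @property
    def dose_ug(self) -> float:
        return self.dose_mg * 1000.0


@dataclass(frozen=True)
class SkinStack:
    """Skin layer thicknesses and the sublayer/section discretisation grid.

    Each of SC, ED and DE is split into ``n_sublayers`` sublayers (the dose
    application grid) and each sublayer into ``n_sections`` sections (the
    diffusion grid), so a layer of thickness ``h`` has section thickness
    ``dh = h / (n_sublayers * n_sections)``.
    """

    h_sc_um: float = 21.0
    h_ed_um: float = 72.0
    h_de_um: float = 1500.0
    n_sublayers: int = 4
    n_sections: int = 10

    def __post_init__(self) -> None:
        for name in ("h_sc_um", "h_ed_um", "h_de_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sublayers < 1 or self.n_sections < 1:
            raise ValueError("grid counts must be >= 1")

    @property
    def thickness_um(self) -> dict[str, float]:
        return {"SC": self.h_sc_um, "ED": self.h_ed_um, "DE": self.h_de_um}

    @property
    def total_depth_um(self) -> float:
        return self.h_sc_um + self.h_ed_um + self.h_de_um

    def dh_um(self, layer: str) -> float:
        """Section thickness of one layer (μm)."""
        return self.thickness_um[layer] / (self.n_sublayers * self.n_sections)

    def sublayer_bounds_um(self) -> list[tuple[str, int, float, float]]:
        """Per-sublayer depth intervals ``(layer, sublayer, top, bottom)``.

        Depth is measured from the skin surface downward; intervals are
        half-open ``[top, bottom)`` and strictly increasing through the stack.
        """
        out = []
        depth = 0.0
        for layer in LAYERS:
            h_sub = self.thickness_um[layer] / self.n_sublayers
            for i in range(self.n_sublayers):
                out.append((layer, i, depth, depth + h_sub))
                depth += h_sub
        return out


@dataclass(frozen=True)
class DoseMap:
    """Fraction of the patch dose deposited in each skin sublayer at t = 0."""

    sublayer_fractions: tuple[tuple[str, int, float], ...]
    undeposited_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = sum(f for _, _, f in self.sublayer_fractions) + self.undeposited_fraction
        if any(not 0 <= f <= 1 for _, _, f in self.sublayer_fractions):
            raise ValueError("sublayer fractions must lie in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dose fractions must sum to 1 (got {total!r})")

    @property
    def deposited_fraction(self) -> float:
        return 1.0 - self.undeposited_fraction

    def fraction(self, layer: str, sublayer: int) -> float:
        for lay, sub, f in self.sublayer_fractions:
            if lay == layer and sub == sublayer:
                return f
        return 0.0

    def nonzero(self) -> list[tuple[str, int, float]]:
        return [(lay, sub, f) for lay, sub, f in self.sublayer_fractions if f > 0]


def needle_cumulative_volume(depth_from_tip: float, geom: NeedleGeometry) -> float:
    """Fraction of one needle's volume within ``depth_from_tip`` of the apex.

    A pyramid scales linearly in both lateral directions with distance from
    the apex, so the cumulative volume follows a cube law ``(d / H)**3``.
    Monotone non-decreasing in ``depth_from_tip``.
    """
    if not 0 <= depth_from_tip <= geom.height_um:
        raise ValueError(
            f"depth_from_tip must be in [0, {geom.height_um}] μm, got {depth_from_tip}"
        )
    return (depth_from_tip / geom.height_um) ** 3


def dose_partition(
    geom: NeedleGeometry,
    skin: SkinStack,
    normalisation: Literal["inserted", "total"] = "inserted",
) -> DoseMap:
    """Map the patch dose onto skin sublayers from needle geometry alone.

    The drug is taken as uniformly distributed through the needle volume.
    With the needle tip at depth ``L_ins = f_p * H``, the dose landing in a
    sublayer spanning depths ``[a, b)`` is proportional to the needle volume
    between the two planes at tip distances ``L_ins - b`` and ``L_ins - a``.

    Parameters
    ----------
    normalisation : {"inserted", "total"}
        ``"inserted"``: fractions are of the inserted-tip volume and sum to 1
        (the whole load is treated as delivered).  ``"total"``: fractions are
        of the whole-needle volume; the ``1 - f_p**3`` of volume that never
        enters the skin stays as an inert ``undeposited_fraction``.
    """
    l_ins = geom.inserted_length_um
    if l_ins <= 0:
        raise ValueError("inserted length must be positive")
    if l_ins > skin.total_depth_um:
        raise ValueError(
            f"needle inserts to {l_ins} μm but the skin grid is only "
            f"{skin.total_depth_um} μm deep"
        )
    inserted_vol = needle_cumulative_volume(l_ins, geom)

    raw = []
    for layer, sub, a, b in skin.sublayer_bounds_um():
        if a >= l_ins:
            raw.append((layer, sub, 0.0))
            continue
        upper = needle_cumulative_volume(l_ins - a, geom)
        lower = needle_cumulative_volume(max(l_ins - b, 0.0), geom)
        raw.append((layer, sub, upper - lower))

    if normalisation == "inserted":
        fractions = tuple((lay, sub, f / inserted_vol) for lay, sub, f in raw)
        undeposited = 0.0
    elif normalisation == "total":
        fractions = tuple(raw)
        undeposited = 1.0 - inserted_vol
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")
    # guard against rounding drift before the DoseMap invariant check
    total = sum(f for _, _, f in fractions) + undeposited
    if abs(total - 1.0) > 1e-12:
        fractions = tuple((lay, sub, f / (total - undeposited) * (1 - undeposited))
                          for lay, sub, f in fractions)
    return DoseMap(sublayer_fractions=fractions, undeposited_fraction=undeposited)
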