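"""Derived whole-plant traits from harvest measurements.

Shoot and root dry weights are sums of their components
(DW_Shoot = DW_Leaf + DW_Stem, DW_Root = DW_LR + DW_FR), specific
leaf area is leaf area per unit leaf dry mass (SLA = Area_Leaf /
DW_Leaf, cm²·g⁻¹), and the root weight ratio is the root fraction of
total dry mass (RWR = DW_Root / (DW_Shoot + DW_Root), g·g⁻¹, bounded
in [0, 1]). Ratios are computed per plant before any averaging
(mean of ratios, not ratio of means), which is the convention used
throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, UndefinedTraitError

__all__ = ["PlantHarvest", "DerivedTraits", "derive_traits"]


@dataclass(frozen=True)
class PlantHarvest:
    """Dry weights (g) and leaf area (cm²) for one harvested plant."""

    plant_id: str
    dw_leaf: float
    dw_stem: float
    dw_lr: float
    dw_fr: float
    area_leaf: float

    def __post_init__(self) -> None:
        for name in ("dw_leaf", "dw_stem", "dw_lr", "dw_fr", "area_leaf"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(
                    f"{name} must be finite and >= 0, got {value!r}"
                )


@dataclass(frozen=True)
class DerivedTraits:
    """Per-plant derived traits; see module docstring for formulas."""

    plant_id: str
    dw_shoot: float
    dw_root: float
    sla: float
    rwr: float


def derive_traits(h: PlantHarvest) -> DerivedTraits:
    """Compute DW_Shoot, DW_Root, SLA, and RWR for one plant.

    Raises :class:`UndefinedTraitError` when SLA is requested for a
    plant with leaf area but no leaf mass, or RWR for a plant with no
    dry mass at all.
    """
    dw_shoot = h.dw_leaf + h.dw_stem
    dw_root = h.dw_lr + h.dw_fr
    if h.dw_leaf == 0 and h.area_leaf > 0:
        raise UndefinedTraitError(
            f"plant {h.plant_id!r}: SLA undefined (area_leaf > 0 but dw_leaf = 0)"
        )
    sla = h.area_leaf / h.dw_leaf if h.dw_leaf > 0 else 0.0
    total = dw_shoot + dw_root
    if total == 0:
        raise UndefinedTraitError(
            f"plant {h.plant_id!r}: RWR undefined (total dry weight is zero)"
        )
    return DerivedTraits(
        plant_id=h.plant_id,
        dw_shoot=dw_shoot,
        dw_root=dw_root,
        sla=sla,
        rwr=dw_root / total,
    )
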