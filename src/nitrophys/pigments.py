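"""Spectrophotometric pigment quantification.

Chlorophyll a, chlorophyll b, and total carotenoid concentrations
(μg·mL⁻¹ of extract) are computed from multiwavelength absorbance
readings with Lichtenthaler-style equations; relative anthocyanin
content is the 530−600 nm absorbance difference normalised per gram of
fresh tissue (ΔOD·g⁻¹). Concentrations are converted to a fresh-weight
basis (mg per 100 g) using the extraction volume, dilution factor, and
sample mass.

Negative pigment values can arise from pathological absorbance
combinations (e.g. turbid or degraded extracts); they are returned
as-is with a :class:`PigmentWarning` so that downstream QC can flag the
extract, rather than being silently clamped to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "AbsorbanceRecord",
    "PigmentResult",
    "PigmentWarning",
    "chlorophyll_a",
    "chlorophyll_b",
    "carotenoids",
    "content_fresh_weight",
    "anthocyanin",
    "quantify_pigments",
]

#: μg·g⁻¹ → mg·100g⁻¹ (1 μg·g⁻¹ = 100 μg / 100 g = 0.1 mg / 100 g)
_UG_PER_G_TO_MG_PER_100G = 0.1


class PigmentWarning(UserWarning):
    """Raised (as a warning) for physically suspicious pigment values."""


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Raw spectrophotometer readings for one leaf extract.

    Parameters
    ----------
    a663_2, a646_8, a470, a530, a600
        Optical densities at the named wavelengths (nm); dimensionless,
        finite, non-negative.
    sample_mass
        Fresh mass of the extracted tissue, g (> 0).
    extraction_volume
        Solvent volume, mL (> 0).
    dilution_factor
        Dilution applied before reading (≥ 1).
    """

    a663_2: float
    a646_8: float
    a470: float = 0.0
    a530: float = 0.0
    a600: float = 0.0
    sample_mass: float = 1.0
    extraction_volume: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a663_2", "a646_8", "a470", "a530", "a600"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidInputError(f"absorbance {name} must be finite, got {value!r}")
            if value < 0:
                raise InvalidInputError(f"absorbance {name} must be >= 0, got {value}")
        if not math.isfinite(self.sample_mass) or self.sample_mass <= 0:
            raise InvalidInputError(f"sample_mass must be > 0, got {self.sample_mass}")
        if not math.isfinite(self.extraction_volume) or self.extraction_volume <= 0:
            raise InvalidInputError(
                f"extraction_volume must be > 0, got {self.extraction_volume}"
            )
        if not math.isfinite(self.dilution_factor) or self.dilution_factor < 1:
            raise InvalidInputError(
                f"dilution_factor must be >= 1, got {self.dilution_factor}"
            )


@dataclass(frozen=True)
class PigmentResult:
    """Pigment quantities for one extract.

    Concentrations (``*_conc``) are μg·mL⁻¹ of extract; fresh-weight
    contents (``*_fw``) are mg·100g⁻¹; ``acn`` is ΔOD·g⁻¹.
    ``chl_fw`` is exactly ``chl_a_fw + chl_b_fw``.
    """

    chl_a_conc: float
    chl_b_conc: float
    ctd_conc: float
    chl_a_fw: float
    chl_b_fw: float
    chl_fw: float
    ctd_fw: float
    acn: float


def _warn_if_negative(value: float, label: str) -> float:
    if value < 0:
        warnings.warn(
            f"{label} is negative ({value:.4g}); check the extract quality",
            PigmentWarning,
            stacklevel=3,
        )
    return value


def chlorophyll_a(rec: AbsorbanceRecord) -> float:
    """Chlorophyll-a concentration, μg·mL⁻¹: 12.25·A663.2 − 2.79·A646.8."""
    return _warn_if_negative(12.25 * rec.a663_2 - 2.79 * rec.a646_8, "chlorophyll a")


def chlorophyll_b(rec: AbsorbanceRecord) -> float:
    """Chlorophyll-b concentration, μg·mL⁻¹: 21.5·A646.8 − 5.1·A663.2."""
    return _warn_if_negative(21.5 * rec.a646_8 - 5.1 * rec.a663_2, "chlorophyll b")


def carotenoids(rec: AbsorbanceRecord) -> float:
    """Total carotenoid concentration, μg·mL⁻¹.

    (1000·A470 − 1.8·CHLa − 85.02·CHLb) / 198, with the chlorophylls
    computed from the same record.
    """
    chl_a = 12.25 * rec.a663_2 - 2.79 * rec.a646_8
    chl_b = 21.5 * rec.a646_8 - 5.1 * rec.a663_2
    ctd = (1000.0 * rec.a470 - 1.8 * chl_a - 85.02 * chl_b) / 198.0
    return _warn_if_negative(ctd, "carotenoids")


def content_fresh_weight(conc: float, rec: AbsorbanceRecord) -> float:
    """Convert an extract concentration to a fresh-weight content.

    ``conc`` (μg·mL⁻¹) × extraction volume (mL) × dilution factor /
    sample mass (g) gives μg·g⁻¹, scaled by 0.1 to mg·100g⁻¹.
    """
    if not math.isfinite(conc):
        raise InvalidInputError(f"concentration must be finite, got {conc!r}")
    ug_per_g = conc * rec.extraction_volume * rec.dilution_factor / rec.sample_mass
    return ug_per_g * _UG_PER_G_TO_MG_PER_100G


def anthocyanin(rec: AbsorbanceRecord) -> float:
    """Relative anthocyanin content, ΔOD·g⁻¹.

    The 530−600 nm absorbance difference, scaled by extraction volume
    and dilution factor and normalised by sample mass so the result is
    per gram of fresh tissue. With the default volume/dilution of 1
    this reduces to (A530 − A600)/mass.
    """
    return (
        (rec.a530 - rec.a600)
        * rec.extraction_volume
        * rec.dilution_factor
        / rec.sample_mass
    )


def quantify_pigments(rec: AbsorbanceRecord) -> PigmentResult:
    """Compute all pigment quantities for one extract."""
    chl_a = chlorophyll_a(rec)
    chl_b = chlorophyll_b(rec)
    ctd = carotenoids(rec)
    chl_a_fw = content_fresh_weight(chl_a, rec)
    chl_b_fw = content_fresh_weight(chl_b, rec)
    return PigmentResult(
        chl_a_conc=chl_a,
        chl_b_conc=chl_b,
        ctd_conc=ctd,
        chl_a_fw=chl_a_fw,
        chl_b_fw=chl_b_fw,
        chl_fw=chl_a_fw + chl_b_fw,
        ctd_fw=content_fresh_weight(ctd, rec),
        acn=anthocyanin(rec),
    )
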