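"""Noradrenaline infusion preparation and dose-unit bridging.

The institution doses noradrenaline in mg/h from a standard syringe
preparation (a 5 mg / 5 mL vial diluted to 50 mL, i.e. 0.1 mg/mL), while
the shock-severity literature expresses dose in ug/kg/min.  This module
holds the arithmetic connecting the two, plus the literature shock bands.
The shock band is informational only: the scale's noradrenaline points come
from the institutional mg/h bands in :mod:`costas.scoring`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InfusionPreparation",
    "ShockBand",
    "SHOCK_BANDS",
    "prepare_infusion",
    "dose_to_rate",
    "convert_dose",
    "rate_to_dose",
    "wkm_to_mg_per_h",
    "shock_band",
]


@dataclass(frozen=True)
class InfusionPreparation:
    """A prepared syringe: drug mass, volumes and resulting concentration."""

    drug_mass_mg: float
    vial_volume_ml: float
    diluent_volume_ml: float

    @property
    def total_volume_ml(self) -> float:
        return self.vial_volume_ml + self.diluent_volume_ml

    @property
    def concentration_mg_per_ml(self) -> float:
        return self.drug_mass_mg / self.total_volume_ml


@dataclass(frozen=True)
class ShockBand:
    """One literature shock-severity stratum in ug/kg/min."""

    label: str
    lower: float  # inclusive
    upper: float  # exclusive


#: Approximate literature strata for norepinephrine requirement; the
#: cut-offs are empirical and lack universal consensus.  Boundary points
#: fall to the higher-severity side, matching the "<0.1" lower band.
SHOCK_BANDS: tuple[ShockBand, ...] = (
    ShockBand("mild", 0.0, 0.1),
    ShockBand("moderate", 0.1, 0.3),
    ShockBand("severe", 0.3, 0.5),
    ShockBand("refractory", 0.5, float("inf")),
)

#: Upper edge of the printed refractory range; doses beyond it are flagged.
SHOCK_PRINTED_MAX_WKM = 1.0


def prepare_infusion(
    drug_mass_mg: float, vial_volume_ml: float, diluent_volume_ml: float = 0.0
) -> InfusionPreparation:
    """Describe the infusion obtained by diluting a vial.

    The standard institutional preparation is ``prepare_infusion(5, 5, 45)``:
    a 5 mg / 5 mL vial diluted to 50 mL with 0.9% saline, 0.1 mg/mL.
    """
    if drug_mass_mg <= 0:
        raise ValueError("drug mass must be positive")
    if vial_volume_ml <= 0:
        raise ValueError("vial volume must be positive")
    if diluent_volume_ml < 0:
        raise ValueError("diluent volume must be non-negative")
    return InfusionPreparation(drug_mass_mg, vial_volume_ml, diluent_volume_ml)


def dose_to_rate(dose_mg_per_h: float, concentration_mg_per_ml: float = 0.1) -> float:
    """Pump rate in mL/h delivering ``dose_mg_per_h`` at a concentration."""
    if concentration_mg_per_ml <= 0:
        raise ValueError("concentration must be positive")
    if dose_mg_per_h < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg_per_h / concentration_mg_per_ml


def convert_dose(dose_mg_per_h: float, weight_kg: float) -> float:
    """Convert an mg/h dose to the weight-based ug/kg/min scale."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if dose_mg_per_h < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg_per_h * 1000.0 / 60.0 / weight_kg


def wkm_to_mg_per_h(dose_wkm: float, weight_kg: float) -> float:
    """Inverse of :func:`convert_dose`: ug/kg/min back to mg/h."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return dose_wkm * weight_kg * 60.0 / 1000.0


def rate_to_dose(rate_ml_per_h: float, concentration_mg_per_ml: float = 0.1) -> float:
    """Drug delivery in mg/h from a pump rate and concentration."""
    if concentration_mg_per_ml <= 0:
        raise ValueError("concentration must be positive")
    return rate_ml_per_h * concentration_mg_per_ml


def shock_band(dose_wkm: float) -> tuple[str, tuple[str, ...]]:
    """Literature shock-severity label for a ug/kg/min dose.

    Returns ``(label, flags)``; doses above the printed refractory ceiling
    keep the ``refractory`` label with an ``above_printed_range`` flag.
    """
    if dose_wkm < 0:
        raise ValueError("dose must be non-negative")
    for band in SHOCK_BANDS:
        if band.lower <= dose_wkm < band.upper:
            flags = ("above_printed_range",) if dose_wkm > SHOCK_PRINTED_MAX_WKM else ()
            return band.label, flags
    raise AssertionError("unreachable: bands cover [0, inf)")
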