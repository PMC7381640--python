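"""Closed-form dose and radiological hazard calculus.

All quantities follow the standard environmental-radiometry conventions:

* OAED = D_air x 0.7 x 8760 x 0.2 x 1e-6   (mSv year^-1)
* IAED = D_air x 0.7 x 8760 x 0.8 x 1e-6
* D_soil = 0.43 A_U + 0.666 A_Th + 0.042 A_K   (nGy h^-1)
* Ra_eq = A_U + 1.43 A_Th + 0.077 A_K   (Bq kg^-1)
* H_ex = A_U/370 + A_Th/259 + A_K/4810  (<= 1 acceptable)

with D_air the absorbed dose rate in air 1 m above ground in nGy h^-1 and
activities in Bq kg^-1.  Internal math is never rounded; presentation
rounding (doses to 2 decimals, dose rates to integers, ratios to 1 decimal)
lives in the reporting layer only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .types import ActivityTriplet, HazardAssessment


@dataclass(frozen=True)
class DoseCoefficients:
    """Dose-conversion constants of the annual-effective-dose formulas."""

    sv_per_gy: float = constants.DOSE_CONVERSION_SV_PER_GY
    occupancy_indoor: float = constants.OCCUPANCY_INDOOR
    occupancy_outdoor: float = constants.OCCUPANCY_OUTDOOR
    hours_per_year: float = constants.HOURS_PER_YEAR
    soil_u: float = constants.SOIL_DOSE_COEFF["U"]
    soil_th: float = constants.SOIL_DOSE_COEFF["Th"]
    soil_k: float = constants.SOIL_DOSE_COEFF["K"]

    def __post_init__(self) -> None:
        if not math.isclose(self.occupancy_indoor + self.occupancy_outdoor, 1.0):
            raise ValueError("occupancy factors must sum to 1")
        for name in ("sv_per_gy", "hours_per_year", "soil_u", "soil_th", "soil_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"coefficient must be positive: {name}")


@dataclass(frozen=True)
class HazardCoefficients:
    """Radium-equivalent weights and external-hazard-index denominators."""

    ra_eq_u: float = constants.RA_EQ_WEIGHTS["U"]
    ra_eq_th: float = constants.RA_EQ_WEIGHTS["Th"]
    ra_eq_k: float = constants.RA_EQ_WEIGHTS["K"]
    h_ex_u: float = constants.H_EX_DENOMINATORS["U"]
    h_ex_th: float = constants.H_EX_DENOMINATORS["Th"]
    h_ex_k: float = constants.H_EX_DENOMINATORS["K"]
    limit: float = constants.H_EX_LIMIT


DEFAULT_DOSE = DoseCoefficients()
DEFAULT_HAZARD = HazardCoefficients()


def oaed(d_air: float, c: DoseCoefficients = DEFAULT_DOSE) -> float:
    """Annual outdoor effective dose, mSv year^-1."""
    if d_air < 0:
        raise ValueError("negative dose rate")
    return d_air * c.sv_per_gy * c.hours_per_year * c.occupancy_outdoor * 1e-6


def iaed(d_air: float, c: DoseCoefficients = DEFAULT_DOSE) -> float:
    """Annual indoor effective dose, mSv year^-1."""
    if d_air < 0:
        raise ValueError("negative dose rate")
    return d_air * c.sv_per_gy * c.hours_per_year * c.occupancy_indoor * 1e-6


def total_aed(d_air: float, c: DoseCoefficients = DEFAULT_DOSE) -> float:
    return oaed(d_air, c) + iaed(d_air, c)


def dose_from_soil(
    a: ActivityTriplet, c: DoseCoefficients = DEFAULT_DOSE
) -> float:
    """Absorbed dose rate in air 1 m above ground from soil activities, nGy h^-1."""
    return c.soil_u * a.a_u + c.soil_th * a.a_th + c.soil_k * a.a_k


def radium_equivalent(
    a: ActivityTriplet, h: HazardCoefficients = DEFAULT_HAZARD
) -> float:
    """Radium equivalent activity, Bq kg^-1."""
    return h.ra_eq_u * a.a_u + h.ra_eq_th * a.a_th + h.ra_eq_k * a.a_k


def external_hazard_index(
    a: ActivityTriplet, h: HazardCoefficients = DEFAULT_HAZARD
) -> tuple[float, bool]:
    """External hazard index and whether it exceeds the unity limit."""
    value = a.a_u / h.h_ex_u + a.a_th / h.h_ex_th + a.a_k / h.h_ex_k
    return value, value > h.limit


def ratio_of_difference(d_direct: float, d_soil: float) -> float:
    """Direct-measurement / soil-concentration dose-rate ratio.

    Below 1 the built-up environment shields terrestrial gammas; above 1 the
    building materials act as additional sources.
    """
    if d_soil <= 0:
        raise ValueError("soil dose rate must be positive")
    if d_direct < 0:
        raise ValueError("negative direct dose rate")
    return d_direct / d_soil


def classify_builtup(ratio: float, neutral_band: float = 0.0) -> str:
    """Classify a difference ratio: shielding- vs source-dominated, with an
    optional neutrality band around unity."""
    if ratio < 1.0 - neutral_band:
        return "shielding-dominated"
    if ratio > 1.0 + neutral_band:
        return "source-dominated"
    return "neutral"


def combined_relative_uncertainty(components) -> float:
    """Root-sum-of-squares combination of relative standard uncertainties."""
    comps = np.asarray(list(components), dtype=float)
    if comps.size == 0:
        return 0.0
    if np.any(comps < 0):
        raise ValueError("relative uncertainties must be non-negative")
    return float(np.sqrt((comps**2).sum()))


def within_reference_band(
    total_aed_msv: float,
    band: tuple[float, float] = constants.REFERENCE_LEVEL_BAND_MSV,
) -> bool:
    """Whether a total AED sits below the lower edge of the existing-exposure
    reference band (i.e. no new radiological risk)."""
    return total_aed_msv < band[0]


def assess_site(
    activity: ActivityTriplet | None = None,
    d_air_direct: float | None = None,
    d_air_soil: float | None = None,
    site_id: str = "",
    region: str = "",
    dose_coeffs: DoseCoefficients = DEFAULT_DOSE,
    hazard_coeffs: HazardCoefficients = DEFAULT_HAZARD,
) -> HazardAssessment:
    """Full hazard assessment for one site.

    AEDs are computed from the direct dose rate when available, otherwise
    from the soil-derived dose rate; the hazard indices require activities.
    """
    if activity is not None and d_air_soil is None:
        d_air_soil = dose_from_soil(activity, dose_coeffs)
    d_for_aed = d_air_direct if d_air_direct is not None else d_air_soil
    out = HazardAssessment(
        d_air_direct=d_air_direct,
        d_air_soil=d_air_soil,
        site_id=site_id,
        region=region,
    )
    if d_for_aed is not None:
        out.oaed = oaed(d_for_aed, dose_coeffs)
        out.iaed = iaed(d_for_aed, dose_coeffs)
        out.total_aed = out.oaed + out.iaed
        out.within_reference_band = within_reference_band(out.total_aed)
    if activity is not None:
        out.ra_eq = radium_equivalent(activity, hazard_coeffs)
        out.h_ex, out.exceeds_limit = external_hazard_index(activity, hazard_coeffs)
    if d_air_direct is not None and d_air_soil is not None and d_air_soil > 0:
        out.ratio_of_difference = ratio_of_difference(d_air_direct, d_air_soil)
    return out
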